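"""Configuration-driven orchestration of all analysis stages.

:func:`run_pipeline` executes the stages named in a config (a dict, or a
YAML file with the same structure) in declared order, writes each stage's
tables under the output directory and returns a run manifest listing every
output file with its SHA-256 checksum.  A single global seed deterministically
derives one sub-seed per stage (``SeedSequence([seed, stage_index])``), so a
rerun with an identical config reproduces identical checksums.

Config schema (all sections optional; unknown keys are rejected)::

    seed: 1
    out_dir: runs/demo
    stages: [collisions, morphometry, spectra, eds, variants, expression]
    collisions:  {n_samples: 100000}
    morphometry: {input: null}          # null -> synthetic
    spectra:     {}
    eds:         {}
    variants:    {}
    expression:  {basemean_min: 100.0}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import assays, collisions, expression, morphometry, synthetic, variants

__all__ = ["run_pipeline", "load_config", "validate_config", "STAGES"]

#: Canonical stage order; also fixes per-stage seed derivation.
STAGES = ("collisions", "morphometry", "spectra", "eds", "variants", "expression")

_TOP_KEYS = {"seed", "out_dir", "stages", *STAGES}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Reject unknown keys, unknown stages and dangling input paths."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    for stage in stages:
        block = config.get(stage) or {}
        if not isinstance(block, dict):
            raise ValueError(f"config section {stage!r} must be a mapping")
        path = block.get("input")
        if path is not None and not Path(path).exists():
            raise ValueError(f"stage {stage!r}: input path {path!r} does not exist")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1, np.uint32)[0] % 2**31)


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def _stage_collisions(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    summary, samples = collisions.pressure_distribution_mc(
        n_samples=int(block.get("n_samples", 100_000)), seed=seed, return_samples=True
    )
    rows = {
        "n_samples": summary.n_samples,
        "seed": summary.seed,
        "pressure_min_pa": summary.pressure_min,
        "pressure_max_pa": summary.pressure_max,
        **{f"p{int(q)}_pa": v for q, v in summary.percentiles.items()},
        "ratio_to_turgor_max": summary.ratio_to_turgor_max,
        "ratio_to_young_max": summary.ratio_to_young_max,
        "fraction_exceeding_turgor": summary.fraction_exceeding_turgor,
    }
    paths = [_write_tsv(pd.DataFrame([rows]), out / "pressure_summary.tsv")]
    if block.get("write_samples", False):
        cols = ["tip_radius_m", "v_normal_ms", "e_star_pa", "p_mean_pa", "p0_pa", "hertz_valid"]
        paths.append(_write_tsv(pd.DataFrame({c: samples[c] for c in cols}), out / "pressure_samples.tsv"))
    return paths, {"pressure_max_gpa": summary.pressure_max / 1e9}


def _stage_morphometry(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    if block.get("input"):
        table = pd.read_csv(block["input"], sep="\t")
    else:
        table = synthetic.gen_morphometry(seed=seed)
    measure = block.get("measure", "aspect_ratio")
    summaries = morphometry.summarize_morphometry(table, measure)
    sdf = pd.DataFrame(
        [{"group": s.group, "n": s.n, "mean": s.mean, "sd": s.sd, "sem": s.sem} for s in summaries.values()]
    )
    groups = block.get("groups", sorted(summaries))
    test = morphometry.unpaired_t_test(
        summaries[groups[0]], summaries[groups[1]], method=block.get("method", "student")
    )
    tdf = pd.DataFrame(
        [{"group_a": groups[0], "group_b": groups[1], "t": test.statistic,
          "df": test.df, "pvalue": test.pvalue, "method": test.method, "stars": test.stars}]
    )
    paths = [
        _write_tsv(table, out / "morphometry.tsv"),
        _write_tsv(sdf, out / "morphometry_summary.tsv"),
        _write_tsv(tdf, out / "morphometry_test.tsv"),
    ]
    return paths, {"pvalue": test.pvalue}


def _stage_spectra(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    if block.get("input"):
        spec = assays.Spectrum.from_table(pd.read_csv(block["input"], sep="\t"))
    else:
        spec = synthetic.gen_spectra(seed=seed)
    result = assays.gram_stain_index(spec, threshold=float(block.get("threshold", 1.0)))
    paths = [
        _write_tsv(
            pd.DataFrame({"wavelength_nm": spec.wavelength, "absorbance": spec.absorbance}),
            out / "spectrum.tsv",
        ),
        _write_tsv(pd.DataFrame([dataclasses.asdict(result)]), out / "gram_index.tsv"),
    ]
    return paths, {"gram_index": result.index, "classification": result.classification}


def _stage_eds(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    if block.get("input"):
        table = pd.read_csv(block["input"], sep="\t")
    else:
        table = synthetic.gen_eds_table(seed=seed)
    result = assays.eds_density_change(
        table[table["group"] == "control"], table[table["group"] == "treated"], seed=seed
    )
    paths = [
        _write_tsv(table, out / "eds.tsv"),
        _write_tsv(pd.DataFrame([dataclasses.asdict(result)]), out / "eds_density.tsv"),
    ]
    return paths, {"percent_change": result.percent_change}


def _stage_variants(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    vcf_dir = out / "vcf"
    paths_by_slot = synthetic.gen_vcf_set(seed=seed, out_dir=vcf_dir)
    call_sets = {slot: variants.read_variants(str(p)) for slot, p in paths_by_slot.items()}
    consensus = variants.consensus_intersect(call_sets, snp_only=bool(block.get("snp_only", True)))
    callers = sorted({c for c, _ in call_sets})
    venn = variants.caller_venn(
        set().union(*(call_sets[(callers[0], r)] for r in (1, 2, 3))),
        set().union(*(call_sets[(callers[1], r)] for r in (1, 2, 3))),
    )
    vdf = pd.DataFrame([{"only_a": venn.only_a, "shared": venn.shared, "only_b": venn.only_b}])
    paths = list(paths_by_slot.values()) + [vcf_dir / "truth.tsv"]
    paths += [
        _write_tsv(consensus.to_frame(), out / "consensus_snps.tsv"),
        _write_tsv(vdf, out / "caller_venn.tsv"),
    ]
    return paths, {"n_consensus": len(consensus)}


def _stage_expression(block: dict, seed: int, out: Path) -> tuple[list[Path], dict]:
    if block.get("input"):
        table = pd.read_csv(block["input"], sep="\t")
    else:
        table = synthetic.gen_de_table(seed=seed)
    config = expression.FilterConfig(
        basemean_min=float(block.get("basemean_min", 100.0)),
        padj_max=float(block.get("padj_max", 0.05)),
    )
    table = table.copy()
    table["padj"] = expression.benjamini_hochberg(table["pvalue"].to_numpy())
    passing, counts = expression.filter_de_genes(table, config)
    paths = [
        _write_tsv(table, out / "de_table.tsv"),
        _write_tsv(passing, out / "de_passing.tsv"),
        _write_tsv(pd.DataFrame([counts]), out / "de_counts.tsv"),
    ]
    return paths, counts


_STAGE_RUNNERS: dict[str, Callable[[dict, int, Path], tuple[list[Path], dict]]] = {
    "collisions": _stage_collisions,
    "morphometry": _stage_morphometry,
    "spectra": _stage_spectra,
    "eds": _stage_eds,
    "variants": _stage_variants,
    "expression": _stage_expression,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages and return (and write) the run manifest.

    On a stage failure, the manifest of completed stages is still written to
    ``manifest.json`` before the error propagates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "nanostress_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))

    manifest: dict[str, Any] = {"seed": seed, "stages": []}
    try:
        for stage in stages:
            stage_seed = _stage_seed(seed, stage)
            stage_out = out / stage
            stage_out.mkdir(parents=True, exist_ok=True)
            paths, summary = _STAGE_RUNNERS[stage](config.get(stage) or {}, stage_seed, stage_out)
            manifest["stages"].append(
                {
                    "name": stage,
                    "seed": stage_seed,
                    "outputs": [
                        {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in sorted(paths)
                    ],
                    "summary": summary,
                }
            )
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
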
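"""Seeded synthetic-data generators for every pipeline input.

No public sequencing accessions accompany the study this pipeline emulates,
so each analysis stage is exercised on synthetic inputs whose statistical
structure matches what the stage assumes:

* morphometry: per-cell aspect ratios and wall thicknesses as truncated
  normals at the reported group means/SDs (control ratio 2.44 +/- 0.52,
  treated 1.48 +/- 0.32; wall 15.1 +/- 2.4 nm vs 19.6 +/- 6.7 nm; n = 200);
* Gram-stain spectra: Gaussian dye peaks at 530/590 nm on a linear baseline
  with optional white noise;
* variant call sets: 2 callers x 3 replicates VCF 4.2 files with planted
  6/6-consensus SNPs plus caller-discordant, replicate-discordant and indel
  decoys;
* DE tables: a uniform-null / small-p-alternative p-value mixture with
  log-normal baseMean;
* EDS composition tables: per-cell element weight fractions, with the
  treated periplasm carbon mean shifted by a configured percentage.

Every generator is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

from .assays import Spectrum
from .collisions import _sample_truncnorm

__all__ = [
    "MorphometryGroup",
    "MorphometryConfig",
    "SpectrumConfig",
    "VcfSetConfig",
    "DeTableConfig",
    "EdsConfig",
    "gen_morphometry",
    "gen_spectra",
    "gen_vcf_set",
    "gen_de_table",
    "gen_eds_table",
]


def truncnorm_matched_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying-normal (loc, scale) whose truncation at ``lower`` has the
    requested mean and SD.

    Reported group statistics are sample moments of the actual (truncated)
    population, so the generator matches post-truncation moments rather than
    naively truncating a normal with those parameters -- the naive form is
    biased by sd * phi(alpha)/(1-Phi(alpha)) (~ +0.04 for the treated aspect
    ratio), which would defeat parameter recovery.  When the bound is several
    SDs below the mean the correction is negligible and (mean, sd) is
    returned directly.
    """
    if sd == 0.0:
        return mean, 0.0
    if (mean - lower) / sd > 8.0:  # truncation numerically irrelevant
        return mean, sd

    def moments(params: np.ndarray) -> np.ndarray:
        loc, scale = params
        scale = abs(scale)
        a = (lower - loc) / scale
        m, v = truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd])

    sol = optimize.fsolve(moments, x0=np.array([mean, sd]), full_output=False)
    loc, scale = float(sol[0]), abs(float(sol[1]))
    resid = moments(np.array([loc, scale]))
    if not np.allclose(resid, 0.0, atol=1e-8):
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd}, lower={lower}"
        )
    return loc, scale


def sample_truncnorm_matched(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Truncated-normal samples whose population mean/SD equal ``mean``/``sd``."""
    loc, scale = truncnorm_matched_params(mean, sd, lower)
    return _sample_truncnorm(rng, loc, scale, lower, size)


# ---------------------------------------------------------------- morphometry


@dataclass(frozen=True)
class MorphometryGroup:
    """Generating parameters of one cell population."""

    ratio_mean: float
    ratio_sd: float
    wall_mean: float  # nm
    wall_sd: float
    n: int = 200

    def __post_init__(self) -> None:
        if self.ratio_sd < 0 or self.wall_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.ratio_mean <= 1 or self.wall_mean <= 0:
            raise ValueError("ratio_mean must exceed 1 and wall_mean be positive")
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


#: Reported group parameters: control vs after 72 h of nanorod exposure.
DEFAULT_MORPHOMETRY_GROUPS: dict[str, MorphometryGroup] = {
    "control": MorphometryGroup(ratio_mean=2.44, ratio_sd=0.52, wall_mean=15.1, wall_sd=2.4),
    "treated": MorphometryGroup(ratio_mean=1.48, ratio_sd=0.32, wall_mean=19.6, wall_sd=6.7),
}


@dataclass(frozen=True)
class MorphometryConfig:
    """Groups to simulate plus the cell-width distribution (um).

    Widths are truncated normal; lengths are ``ratio * width`` with the
    per-cell ratio drawn as a truncated normal on (1, inf), so length >= width
    holds by construction.
    """

    groups: dict[str, MorphometryGroup] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOMETRY_GROUPS)
    )
    width_mean: float = 0.9
    width_sd: float = 0.1


def gen_morphometry(config: MorphometryConfig = MorphometryConfig(), seed: int = 0) -> pd.DataFrame:
    """Simulate a tidy morphometry table (cell_id, group, length, width,
    wall_thickness)."""
    rng = np.random.default_rng(seed)
    frames = []
    for group in sorted(config.groups):
        g = config.groups[group]
        ratio = sample_truncnorm_matched(rng, g.ratio_mean, g.ratio_sd, 1.0, g.n)
        width = sample_truncnorm_matched(rng, config.width_mean, config.width_sd, 0.2, g.n)
        wall = sample_truncnorm_matched(rng, g.wall_mean, g.wall_sd, 1e-6, g.n)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{group}_{i:04d}" for i in range(g.n)],
                    "group": group,
                    "length": ratio * width,
                    "width": width,
                    "wall_thickness": wall,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# -------------------------------------------------------------------- spectra


@dataclass(frozen=True)
class SpectrumConfig:
    """Two Gaussian dye peaks on a linear baseline.

    Default amplitudes describe a strongly crystal-violet-retaining sample
    (A590 dominant); set ``amp590`` low and ``amp530`` high for a
    Gram-negative-like spectrum.
    """

    amp590: float = 0.8
    amp530: float = 0.2
    center590: float = 590.0
    center530: float = 530.0
    sigma: float = 20.0
    baseline_intercept: float = 0.05
    baseline_slope: float = -5e-5  # AU per nm
    noise_sd: float = 0.0
    wavelength_start: float = 400.0
    wavelength_stop: float = 750.0
    wavelength_step: float = 1.0


def gen_spectra(config: SpectrumConfig = SpectrumConfig(), seed: int = 0) -> Spectrum:
    """Simulate one absorbance spectrum."""
    if config.sigma <= 0 or config.wavelength_step <= 0:
        raise ValueError("sigma and wavelength_step must be positive")
    wl = np.arange(config.wavelength_start, config.wavelength_stop + 1e-9, config.wavelength_step)
    ab = (
        config.amp590 * np.exp(-0.5 * ((wl - config.center590) / config.sigma) ** 2)
        + config.amp530 * np.exp(-0.5 * ((wl - config.center530) / config.sigma) ** 2)
        + config.baseline_intercept
        + config.baseline_slope * (wl - wl[0])
    )
    if config.noise_sd > 0:
        ab = ab + np.random.default_rng(seed).normal(0.0, config.noise_sd, wl.size)
    return Spectrum(wavelength=wl, absorbance=ab)


# ------------------------------------------------------------------ VCF sets

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VcfSetConfig:
    """Planted-truth design of the 2 caller x 3 replicate VCF fixture.

    ``k_consensus`` SNPs appear in all six call sets; decoys exercise every
    failure mode of the consensus rule: ``n_caller_only`` SNPs seen by one
    caller in all replicates, ``n_replicate_only`` SNPs seen by both callers
    in only a subset of replicates, and ``n_indel`` 6/6-consistent indels
    (removed by ``snp_only``).  Default decoy total of 40 against k = 25
    mirrors a realistically discordant call-set family.
    """

    genome_length: int = 100_000
    k_consensus: int = 25
    n_caller_only: int = 20
    n_replicate_only: int = 15
    n_indel: int = 5
    contig: str = "synthetic_chr"
    callers: tuple[str, str] = ("callerA", "callerB")
    replicates: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        total = self.k_consensus + self.n_caller_only + self.n_replicate_only + self.n_indel
        if total > self.genome_length // 2:
            raise ValueError("too many variants for the genome length")
        if min(self.k_consensus, self.n_caller_only, self.n_replicate_only, self.n_indel) < 0:
            raise ValueError("variant counts must be non-negative")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=nanostress.synthetic
##contig=<ID={contig},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_vcf(path: Path, contig: str, length: int, records: list[tuple[int, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=length))
        for pos, ref, alt in sorted(records):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\n")


def gen_vcf_set(
    config: VcfSetConfig = VcfSetConfig(), seed: int = 0, out_dir: str | Path = "."
) -> dict[tuple[str, int], Path]:
    """Write the six VCF files and return ``{(caller, replicate): path}``.

    Also writes ``truth.tsv`` beside them listing each planted variant and its
    role (consensus / caller_only / replicate_only / indel).
    """
    rng = np.random.default_rng(seed)
    n_total = config.k_consensus + config.n_caller_only + config.n_replicate_only + config.n_indel
    # distinct, non-adjacent positions so indel REF spans never collide
    positions = rng.choice(np.arange(1, config.genome_length - 2, 2), size=n_total, replace=False)
    refs = rng.choice(_BASES, size=n_total)
    alts = np.array([rng.choice([b for b in _BASES if b != r]) for r in refs])

    roles: list[str] = (
        ["consensus"] * config.k_consensus
        + ["caller_only"] * config.n_caller_only
        + ["replicate_only"] * config.n_replicate_only
        + ["indel"] * config.n_indel
    )
    slots = [(c, r) for c in config.callers for r in config.replicates]
    files: dict[tuple[str, int], list[tuple[int, str, str]]] = {s: [] for s in slots}
    truth_rows = []
    for i, role in enumerate(roles):
        pos, ref, alt = int(positions[i]), str(refs[i]), str(alts[i])
        if role == "indel":
            alt = ref + str(rng.choice(_BASES))  # 1 bp insertion, present in all six
            present = slots
        elif role == "consensus":
            present = slots
        elif role == "caller_only":
            caller = config.callers[int(rng.integers(2))]
            present = [(caller, r) for r in config.replicates]
        else:  # replicate_only: both callers, 1 or 2 replicates
            k = int(rng.integers(1, 3))
            reps = rng.choice(config.replicates, size=k, replace=False)
            present = [(c, int(r)) for c in config.callers for r in reps]
        for s in present:
            files[s].append((pos, ref, alt))
        truth_rows.append({"pos": pos, "ref": ref, "alt": alt, "role": role})

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[str, int], Path] = {}
    for (caller, rep), recs in files.items():
        p = out_dir / f"{caller}_rep{rep}.vcf"
        _write_vcf(p, config.contig, config.genome_length, recs)
        paths[(caller, rep)] = p
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths


# ------------------------------------------------------------------ DE tables


@dataclass(frozen=True)
class DeTableConfig:
    """Null/alternative mixture model of a DE result table.

    Null genes (fraction ``pi0``): p ~ Uniform(0,1), log2fc ~ N(0, null_lfc_sd).
    Alternative genes: p ~ Beta(alt_p_shape, 1) concentrated near zero;
    |log2fc| ~ N(effect_log2fc_mean, effect_log2fc_sd), negative with
    probability ``frac_down`` (the stress response studied here is dominated
    by down-regulation).  baseMean is log-normal for all genes.
    """

    m_genes: int = 1000
    pi0: float = 0.9
    alt_p_shape: float = 0.05
    effect_log2fc_mean: float = 2.2
    effect_log2fc_sd: float = 0.2
    null_lfc_sd: float = 0.3
    frac_down: float = 0.9
    basemean_log_mean: float = 5.0
    basemean_log_sd: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.m_genes < 1:
            raise ValueError("m_genes must be >= 1")


def gen_de_table(config: DeTableConfig = DeTableConfig(), seed: int = 0) -> pd.DataFrame:
    """Simulate a DE result table (gene_id, baseMean, log2FoldChange, pvalue,
    is_null)."""
    rng = np.random.default_rng(seed)
    m = config.m_genes
    n_null = int(round(config.pi0 * m))
    is_null = np.zeros(m, dtype=bool)
    is_null[:n_null] = True
    rng.shuffle(is_null)

    p = np.where(
        is_null,
        rng.uniform(0.0, 1.0, m),
        rng.beta(config.alt_p_shape, 1.0, m),
    )
    sign = np.where(rng.uniform(size=m) < config.frac_down, -1.0, 1.0)
    lfc = np.where(
        is_null,
        rng.normal(0.0, config.null_lfc_sd, m),
        sign * np.abs(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, m)),
    )
    base = rng.lognormal(config.basemean_log_mean, config.basemean_log_sd, m)
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(m)],
            "baseMean": base,
            "log2FoldChange": lfc,
            "pvalue": p,
            "is_null": is_null,
        }
    )


# ----------------------------------------------------------------- EDS tables


@dataclass(frozen=True)
class EdsConfig:
    """Per-cell EDS weight-fraction generator.

    Element means describe a typical organic specimen (wt%); the treated
    periplasm mean of ``shifted_element`` is the control mean scaled by
    ``delta_percent``.  Cell counts default to the 22-vs-22 design of the
    emulated microanalysis.
    """

    elements: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"C": (46.0, 2.0), "N": (12.0, 1.5), "O": (25.0, 2.0), "P": (3.0, 0.6)}
    )
    regions: tuple[str, ...] = ("periplasm", "interior")
    delta_percent: float = 15.0
    shifted_element: str = "C"
    shifted_region: str = "periplasm"
    n_control: int = 22
    n_treated: int = 22


def gen_eds_table(config: EdsConfig = EdsConfig(), seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format EDS table (group, cell_id, region, element,
    weight_percent)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("control", config.n_control), ("treated", config.n_treated)):
        for region in config.regions:
            for element, (mean, sd) in sorted(config.elements.items()):
                m = mean
                if (
                    group == "treated"
                    and region == config.shifted_region
                    and element == config.shifted_element
                ):
                    m = mean * (1.0 + config.delta_percent / 100.0)
                vals = np.clip(sample_truncnorm_matched(rng, m, sd, 0.0, n), 0.0, 100.0)
                for i, v in enumerate(vals):
                    rows.append(
                        {
                            "group": group,
                            "cell_id": f"{group}_{i:03d}",
                            "region": region,
                            "element": element,
                            "weight_percent": float(v),
                        }
                    )
    return pd.DataFrame(rows)
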
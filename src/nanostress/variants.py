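"""Multi-caller, multi-replicate SNP consensus filtering and effect
classification.

Population-level resequencing of a stressed bacterial culture yields many
low-confidence variant calls that differ between calling algorithms and
between biological replicates.  The consensus rule implemented here keeps
only variants that appear in *every* one of the 2 callers x 3 replicates
call sets, after normalizing each record to a canonical identity key
``(chrom, pos, ref, alt)``.  Genotype, quality and depth fields are
deliberately ignored: the filter is pure set intersection.

A minimal effect classifier assigns each consensus SNP one of three classes
-- ``intergenic``, ``synonymous`` (silent) or ``missense`` (mismatch) --
by retranslating the affected codon against a gene model with
non-overlapping CDS intervals (1-based, inclusive).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

__all__ = [
    "Variant",
    "ConsensusSet",
    "VennCounts",
    "read_variants",
    "normalize_variant",
    "consensus_intersect",
    "caller_venn",
    "validate_gene_model",
    "classify_snp_effect",
    "EFFECT_CLASSES",
]

EFFECT_CLASSES = ("intergenic", "synonymous", "missense")

_VALID_BASES = frozenset("ACGTN")


class Variant(NamedTuple):
    """Canonical variant identity key (VCF-style, 1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class ConsensusSet:
    """Variants present in all caller x replicate inputs, with provenance counts."""

    variants: frozenset[Variant]
    provenance: Mapping[tuple[str, int], int]

    def __len__(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.variants)
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


class VennCounts(NamedTuple):
    only_a: int
    shared: int
    only_b: int


def normalize_variant(variant: Variant) -> Variant:
    """Canonicalize a variant record.

    Uppercases alleles, trims shared trailing then leading bases (adjusting
    the position for leading trims, i.e. left alignment for simple cases),
    and rejects records whose alleles are identical after folding.  The
    operation is idempotent.
    """
    chrom, pos, ref, alt = variant.chrom, int(variant.pos), variant.ref.upper(), variant.alt.upper()
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if not (set(ref) <= _VALID_BASES and set(alt) <= _VALID_BASES):
        raise ValueError(f"alleles must be ACGTN strings, got {variant.ref!r}/{variant.alt!r}")
    if ref == alt:
        raise ValueError(f"non-variant record at {chrom}:{pos} ({ref}>{alt})")
    # trim shared suffix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"non-variant record at {chrom}:{pos} after trimming")
    return Variant(chrom, pos, ref, alt)


def read_variants(vcf_path: str) -> list[Variant]:
    """Read a VCF 4.x file (plain or bgzipped) into normalized variant keys.

    Multi-allelic records are split into one record per ALT allele before
    normalization.  Caller and replicate identity are metadata supplied by
    the caller of this function, not file content.
    """
    out: list[Variant] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for n, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf, start=1):
            try:
                for alt in rec.alts or ():
                    out.append(normalize_variant(Variant(rec.chrom, rec.pos, rec.ref, alt)))
            except ValueError as exc:
                raise ValueError(f"{vcf_path}: bad record #{n}: {exc}") from exc
    return out


def consensus_intersect(
    inputs: Mapping[tuple[str, int], Iterable[Variant]],
    snp_only: bool = True,
) -> ConsensusSet:
    """Intersect variant sets over every caller x replicate slot.

    ``inputs`` maps ``(caller, replicate)`` to an iterable of (normalized)
    variants and must contain exactly 2 callers x 3 replicates, each caller
    covering the same 3 replicates.  ``snp_only`` drops any record whose ref
    or alt is longer than one base (the filter targets point mutations).
    The result is independent of input order.
    """
    callers = sorted({c for c, _ in inputs})
    replicates = sorted({r for _, r in inputs})
    if len(callers) != 2 or len(replicates) != 3:
        raise ValueError(
            f"need exactly 2 callers x 3 replicates, got callers={callers}, replicates={replicates}"
        )
    missing = [(c, r) for c in callers for r in replicates if (c, r) not in inputs]
    if missing:
        raise ValueError(f"missing caller/replicate slots: {missing}")

    sets: dict[tuple[str, int], frozenset[Variant]] = {}
    for key, variants in inputs.items():
        vs = frozenset(variants)
        if snp_only:
            vs = frozenset(v for v in vs if v.is_snp)
        sets[key] = vs
    consensus = frozenset.intersection(*sets.values())
    provenance = {key: len(vs) for key, vs in sorted(sets.items())}
    return ConsensusSet(variants=consensus, provenance=provenance)


def caller_venn(set_a: Iterable[Variant], set_b: Iterable[Variant]) -> VennCounts:
    """Two-set Venn counts (A only, shared, B only) over variant identity keys."""
    a, b = set(set_a), set(set_b)
    return VennCounts(only_a=len(a - b), shared=len(a & b), only_b=len(b - a))


def validate_gene_model(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a minimal gene-model table.

    Columns: ``chrom``, ``start``, ``end`` (1-based inclusive), ``strand``
    (+/-), ``gene_id``, ``coding`` (bool).  Coding intervals must not overlap
    on the same chromosome and must have length divisible by 3.
    """
    required = {"chrom", "start", "end", "strand", "gene_id", "coding"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene model must have columns {sorted(required)}")
    if not (genes["start"] <= genes["end"]).all():
        raise ValueError("gene intervals must satisfy start <= end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    coding = genes[genes["coding"].astype(bool)]
    for chrom, sub in coding.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping coding intervals on {chrom}")
    return genes


def classify_snp_effect(
    snp: Variant,
    genes: pd.DataFrame,
    reference: Mapping[str, str] | str | Sequence[str],
) -> str:
    """Classify a single-base substitution as intergenic, synonymous or missense.

    ``reference`` is the chromosome sequence (a string, or a mapping from
    chromosome name to sequence) in genome-forward orientation.  The SNP must
    be a 1 bp substitution whose REF base matches the reference at its
    position.  For a SNP inside a coding interval the affected codon is
    translated before and after the substitution with the standard genetic
    code, reverse-complemented first on the minus strand; start/stop codons
    receive no special treatment.
    """
    if not snp.is_snp:
        raise ValueError(f"effect classification requires a 1 bp substitution, got {snp}")
    validate_gene_model(genes)
    seq = reference[snp.chrom] if isinstance(reference, Mapping) else reference
    seq = str(seq).upper()
    if not (1 <= snp.pos <= len(seq)):
        raise ValueError(f"position {snp.pos} outside reference of length {len(seq)}")
    if seq[snp.pos - 1] != snp.ref:
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: expected {snp.ref}, found {seq[snp.pos - 1]}"
        )
    hit = genes[
        (genes["chrom"] == snp.chrom)
        & genes["coding"].astype(bool)
        & (genes["start"] <= snp.pos)
        & (genes["end"] >= snp.pos)
    ]
    if hit.empty:
        return "intergenic"
    gene = hit.iloc[0]
    start, end, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    if (end - start + 1) % 3 != 0:
        raise ValueError(f"CDS length of {gene['gene_id']} is not divisible by 3")
    offset = (snp.pos - start) if strand == "+" else (end - snp.pos)
    codon_index = offset // 3
    if strand == "+":
        cstart = start + 3 * codon_index  # 1-based first base of codon
        codon = seq[cstart - 1 : cstart + 2]
        within = snp.pos - cstart
    else:
        cend = end - 3 * codon_index  # 1-based last genome base == first codon base on -
        codon = seq[cend - 3 : cend]
        within = cend - snp.pos  # position from the right end, genome-forward
    mutated = codon[:within] + snp.alt + codon[within + 1 :] if strand == "+" else (
        codon[: 2 - within] + snp.alt + codon[3 - within :]
    )
    if strand == "-":
        codon = str(Seq(codon).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutated).translate())
    return "synonymous" if aa_before == aa_after else "missense"
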
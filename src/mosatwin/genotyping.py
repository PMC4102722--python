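"""Diploid genotype likelihoods, calls and dataset-level QC statistics.

The likelihood model is the classic per-read mixture: for genotype g = {a1, a2}
each read base b contributes ``L = 1/2 P(b|a1) + 1/2 P(b|a2)`` with
``P(b|a) = 1 - e`` when b == a and ``e/3`` otherwise, where ``e = 10^(-BQ/10)``.
Per-read log-likelihoods are summed and reported phred-scaled, normalised so
the best genotype scores 0. Posteriors over the ten diploid genotypes use a
flat prior by default; a heterozygosity-weighted prior is available but off,
so results carry no hidden constants.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import Interval, SitePileup, VariantRecord

BASES = ("A", "C", "G", "T")
#: the ten unordered diploid genotypes in canonical order
GENOTYPES: tuple[tuple[str, str], ...] = tuple(
    (BASES[i], BASES[j]) for i in range(4) for j in range(i, 4)
)
_GT_INDEX = {g: k for k, g in enumerate(GENOTYPES)}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

DEFAULT_MIN_MQ = 10
DEFAULT_MAX_DEPTH = 500
LOW_CONFIDENCE_DEPTH = 8  # below this a call is flagged, mirroring >=8x QC


@dataclasses.dataclass
class GenotypeCall:
    """A called diploid genotype with its ten phred-scaled likelihoods."""

    contig: str
    pos: int
    genotype: tuple[str, str]
    phred_likelihoods: np.ndarray  # length 10, min exactly 0
    depth: int
    quality: float  # phred gap between best and second-best genotype
    low_confidence: bool = False

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    def posteriors(self) -> np.ndarray:
        """Flat-prior posterior over the ten genotypes (sums to 1)."""
        ll = -self.phred_likelihoods / 10.0  # log10 likelihood, max 0
        w = 10.0 ** (ll - ll.max())
        return w / w.sum()


def _genotype_index(a1: str, a2: str) -> int:
    return _GT_INDEX[(a1, a2) if a1 <= a2 else (a2, a1)]


def genotype_likelihoods(
    pileup: SitePileup,
    min_mq: int = DEFAULT_MIN_MQ,
    max_depth: int = DEFAULT_MAX_DEPTH,
    prior: str = "flat",
    theta: float = 0.001,
) -> GenotypeCall | None:
    """Compute the ten-genotype likelihoods for one site pileup.

    Reads with mapping quality below ``min_mq`` are discarded first; if no
    usable read remains the site is a no-call and ``None`` is returned
    (deliberately distinct from a confident hom-ref call). At most
    ``max_depth`` reads are used, which bounds the numerics — beyond that the
    posterior is saturated anyway.
    """
    keep = pileup.map_quals >= min_mq
    bases = pileup.bases[keep]
    bq = pileup.base_quals[keep]
    known = bases != "N"
    bases, bq = bases[known], bq[known]
    if bases.size == 0:
        return None
    if bases.size > max_depth:
        bases, bq = bases[:max_depth], bq[:max_depth]

    e = 10.0 ** (-bq / 10.0)  # per-read error probability
    # P(b|a): (n_reads, 4); correct base -> 1-e, each wrong base -> e/3
    base_idx = np.searchsorted(np.array(BASES), bases)
    p_given = np.tile((e / 3.0)[:, None], (1, 4))
    p_given[np.arange(bases.size), base_idx] = 1.0 - e
    # per-read genotype likelihood is the mean of the two allele columns
    ll = np.empty(10)
    for k, (a1, a2) in enumerate(GENOTYPES):
        pr = 0.5 * (p_given[:, BASES.index(a1)] + p_given[:, BASES.index(a2)])
        ll[k] = np.log10(pr).sum()
    if prior == "het":
        # heterozygosity-weighted prior: heterozygotes downweighted to theta
        log_prior = np.array(
            [0.0 if a1 == a2 else math.log10(theta) for a1, a2 in GENOTYPES]
        )
        ll = ll + log_prior
    elif prior != "flat":
        raise ValidationError(f"unknown prior {prior!r}")

    pl = -10.0 * (ll - ll.max())
    order = np.argsort(pl, kind="stable")
    best = int(order[0])
    quality = float(pl[order[1]] - pl[order[0]])
    return GenotypeCall(
        contig=pileup.contig,
        pos=pileup.pos,
        genotype=GENOTYPES[best],
        phred_likelihoods=pl,
        depth=int(bases.size),
        quality=quality,
        low_confidence=bases.size < LOW_CONFIDENCE_DEPTH,
    )


def genotype_posteriors(
    pileup: SitePileup, min_mq: int = DEFAULT_MIN_MQ, **kwargs
) -> np.ndarray | None:
    """Flat-prior posterior over the ten genotypes, or None if no-call."""
    call = genotype_likelihoods(pileup, min_mq=min_mq, **kwargs)
    return None if call is None else call.posteriors()


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConcordanceResult:
    fraction: float | None  # None when no comparable site exists
    n_compared: int
    n_concordant: int
    n_nocall: int


def pairwise_concordance(
    calls_a: Mapping[tuple[str, int], GenotypeCall],
    calls_b: Mapping[tuple[str, int], GenotypeCall],
    sites: Iterable[tuple[str, int]] | None = None,
    mode: str = "union",
) -> ConcordanceResult:
    """Fraction of sites with identical unordered genotypes in two call sets.

    ``sites`` defaults to the union (or intersection, per ``mode``) of the two
    call sets' sites. Sites where either side is a no-call are excluded from
    the denominator and counted separately.
    """
    if sites is None:
        a, b = set(calls_a), set(calls_b)
        sites = a | b if mode == "union" else a & b
    n_comp = n_conc = n_nocall = 0
    for site in sites:
        ca, cb = calls_a.get(site), calls_b.get(site)
        if ca is None or cb is None:
            n_nocall += 1
            continue
        n_comp += 1
        if ca.genotype == cb.genotype:
            n_conc += 1
    frac = n_conc / n_comp if n_comp else None
    return ConcordanceResult(frac, n_comp, n_conc, n_nocall)


def titv_ratio(variants: Iterable) -> float | None:
    """Transitions (A<->G, C<->T) over transversions; None if no transversion.

    Accepts (ref, alt) pairs or objects with .ref/.alt attributes.
    """
    ti = tv = 0
    for v in variants:
        ref, alt = (v.ref, v.alt) if hasattr(v, "ref") else (v[0], v[1])
        if (ref, alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


# ---------------------------------------------------------------------------
# coding-effect classification
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def classify_coding_effect(
    variant: VariantRecord,
    gene_model: Sequence,
    reference: Mapping[str, str],
) -> str:
    """Classify a SNV as synonymous/missense/nonsense/non-coding.

    ``gene_model`` holds CDS intervals (0-based half-open) with ``strand`` and
    ``frame`` attributes; the codon containing the variant is reconstructed
    from the reference, reverse-complemented for minus-strand CDS.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValidationError("classify_coding_effect handles SNVs only")
    pos0 = variant.pos - 1
    cds = next(
        (
            iv
            for iv in gene_model
            if iv.contig == variant.contig and iv.start <= pos0 < iv.end
        ),
        None,
    )
    if cds is None:
        return "non-coding"
    seq = reference[variant.contig]
    frame = getattr(cds, "frame", 0) or 0
    strand = getattr(cds, "strand", "+") or "+"
    if strand == "+":
        offset = (pos0 - cds.start - frame) % 3
        codon_start = pos0 - offset
        if codon_start < cds.start or codon_start + 3 > cds.end:
            raise ValidationError(
                f"codon for {variant.contig}:{variant.pos} extends past CDS bounds"
            )
        ref_codon = seq[codon_start : codon_start + 3]
        idx = offset
        alt_base = variant.alt
    else:
        # index from the CDS 3' end (genomic right) on the minus strand
        offset = (cds.end - 1 - pos0 - frame) % 3
        codon_end = pos0 + offset + 1
        if codon_end > cds.end or codon_end - 3 < cds.start:
            raise ValidationError(
                f"codon for {variant.contig}:{variant.pos} extends past CDS bounds"
            )
        genomic = seq[codon_end - 3 : codon_end]
        ref_codon = "".join(_COMPLEMENT[b] for b in reversed(genomic))
        idx = offset
        alt_base = _COMPLEMENT[variant.alt]
    if ref_codon[idx] != (variant.ref if strand == "+" else _COMPLEMENT[variant.ref]):
        raise ValidationError(
            f"reference mismatch at {variant.contig}:{variant.pos}: "
            f"codon has {ref_codon[idx]!r}, variant says {variant.ref!r}"
        )
    alt_codon = ref_codon[:idx] + alt_base + ref_codon[idx + 1 :]
    aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def variant_summary(variants: Sequence[VariantRecord]) -> dict:
    """Per-class counts, Ti/Tv and NS/S for an annotated SNV call set."""
    counts = {"synonymous": 0, "missense": 0, "nonsense": 0, "non-coding": 0}
    for v in variants:
        if v.effect is None:
            raise ValidationError(f"variant {v.contig}:{v.pos} lacks an effect class")
        counts[v.effect] += 1
    syn = counts["synonymous"]
    ns = counts["missense"] + counts["nonsense"]
    return {
        "total": len(variants),
        **counts,
        "titv": titv_ratio(variants) if variants else None,
        "ns_s": ns / syn if syn else None,
    }


def variant_summary_table(variants: Sequence[VariantRecord]):
    import pandas as pd

    return pd.DataFrame([variant_summary(variants)])
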
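"""Somatic-discordance detection between matched samples.

Three detectors run in parallel over per-site pileups of a sample pair, in the
spirit of the tumour/normal callers they emulate:

* ``score`` — a phred-scaled genotype-difference score. With flat-prior
  genotype posteriors P(g | pileup) for each sample, the probability that the
  two samples share a genotype is ``P(same) = sum_g P(g|A) P(g|B)`` and the
  score is ``min(255, -10 log10 P(same))``. A score above 100 therefore means
  the genotypes differ with probability greater than 1 - 10^-10.
* ``fisher`` — a two-sided Fisher's exact test on the 2x2 ref/alt read-count
  table; the pass rule additionally requires the variant allele to be absent
  from the reference sample.
* ``filtered_fisher`` — the same test after per-read base/mapping-quality
  filters, with an allele's count zeroed when its supporting reads stack on
  fewer than a minimum number of distinct start points (a PCR/misalignment
  guard).

Candidates above threshold are then arbitrated: the statistic is recomputed on
realigned pileups (indel-misalignment artifacts collapse), low-coverage
reference samples are flagged, and a cross-sample veto marks calls whose
variant allele also shows up in a held-out sample of the reference twin.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AuditError, ConfigError, ValidationError
from .genotyping import DEFAULT_MIN_MQ, genotype_posteriors
from .io_formats import SitePileup, VariantRecord

SCORE_MAX = 255

SAMPLE_ROLES = ("affected_blood", "affected_biopsy", "healthy_blood", "healthy_biopsy")


@dataclasses.dataclass
class DetectorThresholds:
    """Pass thresholds for the three detectors."""

    score_min: float = 100.0
    p_max: float = 0.01
    require_zero_alt_in_reference: bool = True
    min_mq: int = DEFAULT_MIN_MQ
    filtered_min_bq: int = 20
    filtered_min_mq: int = 20
    min_unique_starts: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.score_min <= SCORE_MAX:
            raise ValidationError("score_min must lie in [0, 255]")
        if not 0 <= self.p_max <= 1:
            raise ValidationError("p_max must lie in [0, 1]")


@dataclasses.dataclass
class DiscordanceCall:
    """One candidate genotype difference between a test and a reference sample."""

    contig: str
    pos: int
    test_sample: str
    ref_sample: str
    detector: str  # score | fisher | filtered_fisher
    statistic: float  # phred score, or p-value for the Fisher detectors
    passes_threshold: bool
    alt: str | None = None
    counts_test: tuple[int, int] | None = None  # (ref, alt)
    counts_ref: tuple[int, int] | None = None
    arbitration: str = "unreviewed"  # artifact | low-coverage | confirmed-candidate

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for cross-method overlap."""
        return (self.contig, self.pos, self.test_sample, self.ref_sample)

    def strength(self) -> float:
        """Larger is stronger evidence, regardless of detector."""
        if self.detector == "score":
            return self.statistic
        # p-values: map to a phred-like scale; p == 0 sorts first
        return float("inf") if self.statistic == 0 else -10.0 * np.log10(self.statistic)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def somatic_score(
    pileup_a: SitePileup, pileup_b: SitePileup, min_mq: int = DEFAULT_MIN_MQ
) -> int | None:
    """Phred-scaled probability that two samples' genotypes differ, in [0, 255].

    Returns ``None`` (a no-score marker, distinct from 0) when either pileup
    yields no usable read after mapping-quality filtering. The raw score is
    rounded to the nearest integer before the 255 cap is applied.
    """
    pa = genotype_posteriors(pileup_a, min_mq=min_mq)
    pb = genotype_posteriors(pileup_b, min_mq=min_mq)
    if pa is None or pb is None:
        return None
    p_same = float(np.dot(pa, pb))
    if p_same <= 0.0:
        return SCORE_MAX
    return min(SCORE_MAX, round(-10.0 * np.log10(p_same)))


def score_to_difference_probability(score: float) -> float:
    """The genotype-difference probability a given score represents."""
    return 1.0 - 10.0 ** (score / -10.0)


def fisher_allele_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float | None:
    """Two-sided Fisher's exact test on a 2x2 (ref, alt) x (sample) table.

    Exact integer arithmetic throughout: under fixed margins the probability
    of drawing ``k`` reference reads in sample A is
    ``C(n_a, k) C(n_b, c_ref - k) / C(n, c_ref)``; the two-sided p-value is
    the sum over all tables whose probability does not exceed the observed
    table's. Returns ``None`` for an all-empty table.
    """
    ref_a, alt_a = counts_a
    ref_b, alt_b = counts_b
    if min(ref_a, alt_a, ref_b, alt_b) < 0:
        raise ValidationError("negative allele counts")
    n_a, n_b = ref_a + alt_a, ref_b + alt_b
    if n_a == 0 or n_b == 0:
        return None
    c_ref = ref_a + ref_b
    n = n_a + n_b
    # integer numerators over the common denominator C(n, c_ref)
    lo, hi = max(0, c_ref - n_b), min(n_a, c_ref)
    obs = comb(n_a, ref_a) * comb(n_b, ref_b)
    total = comb(n, c_ref)
    acc = 0
    for k in range(lo, hi + 1):
        num = comb(n_a, k) * comb(n_b, c_ref - k)
        if num <= obs:
            acc += num
    return float(Fraction(acc, total))


@dataclasses.dataclass
class FilteredFisherResult:
    p_value: float | None
    counts_a: tuple[int, int]
    counts_b: tuple[int, int]


def _filtered_counts(
    pileup: SitePileup, alt: str | None, min_bq: int, min_mq: int, min_unique_starts: int
) -> tuple[int, int]:
    keep = (pileup.base_quals >= min_bq) & (pileup.map_quals >= min_mq)
    bases, starts = pileup.bases[keep], pileup.starts[keep]
    counts = []
    for allele in (pileup.ref_base, alt):
        if allele is None:
            counts.append(0)
            continue
        mask = bases == allele
        n_starts = len(set(starts[mask].tolist()))
        counts.append(0 if n_starts < min_unique_starts else int(mask.sum()))
    return (counts[0], counts[1])


def filtered_fisher_test(
    pileup_a: SitePileup,
    pileup_b: SitePileup,
    alt: str | None,
    min_bq: int = 20,
    min_mq: int = 20,
    min_unique_starts: int = 3,
) -> FilteredFisherResult:
    """Quality-filtered Fisher test; returns the p-value and post-filter table.

    Observations failing the base-/mapping-quality filters are dropped; an
    allele's count is zeroed when its supporting reads span fewer than
    ``min_unique_starts`` distinct start points.
    """
    ca = _filtered_counts(pileup_a, alt, min_bq, min_mq, min_unique_starts)
    cb = _filtered_counts(pileup_b, alt, min_bq, min_mq, min_unique_starts)
    return FilteredFisherResult(fisher_allele_test(ca, cb), ca, cb)


def infer_alt_allele(
    pileups: Sequence[SitePileup], min_mq: int = DEFAULT_MIN_MQ
) -> str | None:
    """Most frequent non-reference base across the given pileups, if any."""
    counter: Counter = Counter()
    for p in pileups:
        keep = p.map_quals >= min_mq
        for b in p.bases[keep].tolist():
            if b != p.ref_base and b != "N":
                counter[b] += 1
    if not counter:
        return None
    # deterministic tie-break: highest count, then lexicographic
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


# ---------------------------------------------------------------------------
# candidate selection and orchestration
# ---------------------------------------------------------------------------

def select_query_positions(
    callset: Sequence[VariantRecord],
    roles: Mapping[str, str],
    max_popfreq: float = 0.20,
) -> list[tuple[str, int]]:
    """Query positions for the four-sample twin design.

    Keeps variant sites that are (a) not called in all four samples, (b) not
    called in both biopsies, (c) not called in both bloods, and (d) at a
    population frequency of at most ``max_popfreq`` (or unknown).
    """
    missing = [r for r in SAMPLE_ROLES if r not in roles]
    if missing:
        raise ConfigError(f"four-sample design requires roles {missing}")
    sample_of = {role: roles[role] for role in SAMPLE_ROLES}
    out: list[tuple[str, int]] = []
    for rec in callset:
        for role, sample in sample_of.items():
            if sample not in rec.genotypes:
                raise ConfigError(
                    f"sample {sample!r} (role {role}) absent from record "
                    f"{rec.contig}:{rec.pos}"
                )
        carrier = {role: rec.carries_alt(sample) for role, sample in sample_of.items()}
        if all(carrier.values()):
            continue
        if carrier["affected_biopsy"] and carrier["healthy_biopsy"]:
            continue
        if carrier["affected_blood"] and carrier["healthy_blood"]:
            continue
        if rec.population_frequency is not None and rec.population_frequency > max_popfreq:
            continue
        out.append((rec.contig, rec.pos))
    return out


PileupSet = Mapping[str, Mapping[tuple[str, int], SitePileup]]


def detect_discordances(
    pileups: PileupSet,
    plan: Sequence[tuple[str, str]],
    thresholds: DetectorThresholds | None = None,
    sites: Iterable[tuple[str, int]] | None = None,
) -> list[DiscordanceCall]:
    """Run all three detectors per site for each (test, reference) pair.

    ``pileups`` maps sample -> site -> pileup; ``plan`` lists ordered sample
    pairs; ``sites`` restricts the scan (defaults to the sites both samples of
    a pair cover). Output order is deterministic: strongest statistic first,
    ties broken by (contig, pos).
    """
    thr = thresholds or DetectorThresholds()
    for test, ref in plan:
        for s in (test, ref):
            if s not in pileups:
                raise ConfigError(f"unknown sample {s!r} in comparison plan")
    calls: list[DiscordanceCall] = []
    for test, ref in plan:
        pair_sites = set(pileups[test]) & set(pileups[ref])
        if sites is not None:
            pair_sites &= set(sites)
        for contig, pos in sorted(pair_sites):
            pa = pileups[test][(contig, pos)]
            pb = pileups[ref][(contig, pos)]
            alt = infer_alt_allele([pa, pb], min_mq=thr.min_mq)
            common = dict(contig=contig, pos=pos, test_sample=test, ref_sample=ref, alt=alt)

            score = somatic_score(pa, pb, min_mq=thr.min_mq)
            if score is not None:
                calls.append(DiscordanceCall(
                    detector="score", statistic=float(score),
                    passes_threshold=score > thr.score_min, **common,
                ))

            ca = pa.allele_counts(alt, min_mq=thr.min_mq) if alt else (pa.depth, 0)
            cb = pb.allele_counts(alt, min_mq=thr.min_mq) if alt else (pb.depth, 0)
            p = fisher_allele_test(ca, cb)
            if p is not None:
                ok = p < thr.p_max
                if thr.require_zero_alt_in_reference:
                    ok = ok and cb[1] == 0
                calls.append(DiscordanceCall(
                    detector="fisher", statistic=p, passes_threshold=ok,
                    counts_test=ca, counts_ref=cb, **common,
                ))

            res = filtered_fisher_test(
                pa, pb, alt, min_bq=thr.filtered_min_bq, min_mq=thr.filtered_min_mq,
                min_unique_starts=thr.min_unique_starts,
            )
            if res.p_value is not None:
                calls.append(DiscordanceCall(
                    detector="filtered_fisher", statistic=res.p_value,
                    passes_threshold=res.p_value < thr.p_max,
                    counts_test=res.counts_a, counts_ref=res.counts_b, **common,
                ))
    calls.sort(key=lambda c: (-c.strength(), c.contig, c.pos, c.detector,
                              c.test_sample, c.ref_sample))
    return calls


def top_k(calls: Iterable[DiscordanceCall], detector: str, k: int,
          pair: tuple[str, str] | None = None) -> list[DiscordanceCall]:
    """Top-k calls of one detector, ranked by strength, ties by (contig, pos)."""
    pool = [c for c in calls if c.detector == detector
            and (pair is None or (c.test_sample, c.ref_sample) == pair)]
    pool.sort(key=lambda c: (-c.strength(), c.contig, c.pos))
    return pool[:k]


def method_overlap(
    calls_by_detector: Mapping[str, Iterable[DiscordanceCall]]
) -> dict[str, int]:
    """Seven-region Venn counts over three detectors' call lists.

    Call identity is (contig, pos, test sample, reference sample). The seven
    region counts sum to the size of the union.
    """
    names = list(calls_by_detector)
    if len(names) != 3:
        raise ConfigError("method_overlap expects exactly three detectors")
    sets = {n: {c.key for c in calls_by_detector[n]} for n in names}
    a, b, c = (sets[n] for n in names)
    regions = {
        f"{names[0]}_only": len(a - b - c),
        f"{names[1]}_only": len(b - a - c),
        f"{names[2]}_only": len(c - a - b),
        f"{names[0]}_{names[1]}": len((a & b) - c),
        f"{names[0]}_{names[2]}": len((a & c) - b),
        f"{names[1]}_{names[2]}": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    regions["union"] = len(a | b | c)
    return regions


# ---------------------------------------------------------------------------
# arbitration
# ---------------------------------------------------------------------------

def _statistic_passes(call: DiscordanceCall, pileups_test: SitePileup,
                      pileups_ref: SitePileup, thr: DetectorThresholds) -> bool:
    """Re-evaluate the candidate's detector on (possibly realigned) pileups."""
    if call.detector == "score":
        s = somatic_score(pileups_test, pileups_ref, min_mq=thr.min_mq)
        return s is not None and s > thr.score_min
    alt = call.alt
    if call.detector == "fisher":
        ca = pileups_test.allele_counts(alt, min_mq=thr.min_mq) if alt else (pileups_test.depth, 0)
        cb = pileups_ref.allele_counts(alt, min_mq=thr.min_mq) if alt else (pileups_ref.depth, 0)
        p = fisher_allele_test(ca, cb)
        ok = p is not None and p < thr.p_max
        if thr.require_zero_alt_in_reference:
            ok = ok and cb[1] == 0
        return ok
    res = filtered_fisher_test(
        pileups_test, pileups_ref, alt, min_bq=thr.filtered_min_bq,
        min_mq=thr.filtered_min_mq, min_unique_starts=thr.min_unique_starts,
    )
    return res.p_value is not None and res.p_value < thr.p_max


def arbitrate_with_realignment(
    candidates: Sequence[DiscordanceCall],
    naive_pileups: PileupSet,
    realigned_pileups: PileupSet,
    thresholds: DetectorThresholds | None = None,
    veto_map: Mapping[tuple[str, str], Sequence[str]] | None = None,
    min_depth: int = 8,
    veto_fraction: float = 0.05,
) -> list[DiscordanceCall]:
    """Assign arbitration verdicts; never promotes a candidate.

    * ``artifact`` — the detector statistic falls below threshold when
      recomputed on realigned pileups (the indel-misalignment signature), or
      the variant allele is seen at >= ``veto_fraction`` in a held-out sample
      named by ``veto_map[(test, ref)]``.
    * ``low-coverage`` — the reference sample has fewer than ``min_depth``
      usable reads, so absence there is uninformative.
    * ``confirmed-candidate`` — everything else.
    """
    thr = thresholds or DetectorThresholds()
    out: list[DiscordanceCall] = []
    for cand in candidates:
        site = cand.site
        re_test = realigned_pileups.get(cand.test_sample, {}).get(site)
        re_ref = realigned_pileups.get(cand.ref_sample, {}).get(site)
        if re_test is None or re_ref is None:
            raise AuditError(
                f"candidate {cand.contig}:{cand.pos} missing from realigned pileups"
            )
        verdict = "confirmed-candidate"
        if not _statistic_passes(cand, re_test, re_ref, thr):
            verdict = "artifact"
        else:
            naive_ref = naive_pileups[cand.ref_sample][site]
            usable = int((naive_ref.map_quals >= thr.min_mq).sum())
            if usable < min_depth:
                verdict = "low-coverage"
            elif veto_map and cand.alt is not None:
                for held_out in veto_map.get((cand.test_sample, cand.ref_sample), ()):
                    pk = naive_pileups.get(held_out, {}).get(site)
                    if pk is None:
                        continue
                    ref_n, alt_n = pk.allele_counts(cand.alt, min_mq=thr.min_mq)
                    total = ref_n + alt_n
                    if total and alt_n / total >= veto_fraction:
                        verdict = "artifact"
                        break
        out.append(dataclasses.replace(cand, arbitration=verdict))
    return out


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TruthEvaluation:
    sensitivity: float | None  # None when nothing was planted
    n_planted: int
    n_recovered: int
    false_discoveries: int
    per_vaf: dict  # vaf -> (recovered, planted)


def evaluate_against_truth(calls: Sequence[DiscordanceCall], truth) -> TruthEvaluation:
    """Sensitivity and false-discovery count of confirmed candidates vs truth.

    A planted somatic event is recovered when a confirmed candidate sits at
    its position; any confirmed candidate elsewhere (germline or artifact
    position included) is a false discovery.
    """
    confirmed = {c.site for c in calls if c.arbitration == "confirmed-candidate"}
    planted = {(e.contig, e.pos): e for e in truth.somatic_events}
    recovered = confirmed & set(planted)
    per_vaf: dict = {}
    for (contig, pos), ev in planted.items():
        hit, tot = per_vaf.get(ev.vaf, (0, 0))
        per_vaf[ev.vaf] = (hit + ((contig, pos) in recovered), tot + 1)
    fd = len(confirmed - set(planted))
    sens = len(recovered) / len(planted) if planted else None
    return TruthEvaluation(
        sensitivity=sens, n_planted=len(planted), n_recovered=len(recovered),
        false_discoveries=fd, per_vaf=per_vaf,
    )
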
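"""Carriership-based disease-susceptibility scoring.

A subject's score is the sum over risk loci of the number of risk-allele
copies carried times the logarithm of the locus' published odds ratio,
``score = sum_j c_j ln(OR_j)`` with c_j in {0, 1, 2}. The score only becomes
interpretable relative to a control cohort scored over the *same* locus
subset, so every distribution carries a hash of its locus ids and percentile
lookups refuse cross-subset comparisons. Under Hardy-Weinberg equilibrium the
control-score mean has the closed form ``sum_j 2 f_j ln(OR_j)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComparabilityError, ValidationError


@dataclasses.dataclass(frozen=True)
class RiskLocus:
    locus_id: str
    contig: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    risk_allele_freq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.odds_ratio) and self.odds_ratio > 0):
            raise ValidationError(
                f"odds ratio of {self.locus_id} must be finite and positive"
            )


@dataclasses.dataclass
class RiskModel:
    loci: list[RiskLocus]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("risk model has duplicate locus ids")
        self._by_id = {l.locus_id: l for l in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, locus_id: str) -> RiskLocus:
        return self._by_id[locus_id]

    def subset(self, locus_ids: Sequence[str]) -> "RiskModel":
        return RiskModel([self._by_id[i] for i in locus_ids])

    def subset_hash(self) -> str:
        """Identity of the locus subset; guards percentile comparability."""
        joined = ",".join(sorted(l.locus_id for l in self.loci))
        return hashlib.sha1(joined.encode()).hexdigest()[:12]

    def log_odds(self, base: float = math.e) -> np.ndarray:
        return np.array([math.log(l.odds_ratio, base) for l in self.loci])

    def expected_control_mean(self, base: float = math.e) -> float:
        """Closed-form HWE control-score mean, sum_j 2 f_j log(OR_j)."""
        return float(
            sum(2 * l.risk_allele_freq * math.log(l.odds_ratio, base) for l in self.loci)
        )

    def expected_control_var(self, base: float = math.e) -> float:
        return float(
            sum(
                (math.log(l.odds_ratio, base) ** 2)
                * 2 * l.risk_allele_freq * (1 - l.risk_allele_freq)
                for l in self.loci
            )
        )


@dataclasses.dataclass
class RiskScore:
    subject: str
    score: float
    n_loci_used: int
    n_loci_missing: int
    subset_hash: str
    percentile: float | None = None
    cohort_name: str | None = None


def _copies(genotype, locus: RiskLocus) -> int:
    """Risk-allele copies from either an int count or an allele pair."""
    if isinstance(genotype, (int, np.integer)):
        if not 0 <= int(genotype) <= 2:
            raise ValidationError(
                f"copy count {genotype} at {locus.locus_id} outside 0..2"
            )
        return int(genotype)
    allowed = {locus.risk_allele, locus.other_allele}
    if not set(genotype) <= allowed:
        raise ValidationError(
            f"genotype {tuple(genotype)} at {locus.locus_id} uses alleles outside "
            f"{{risk, other}} = {sorted(allowed)}"
        )
    return sum(1 for a in genotype if a == locus.risk_allele)


def risk_sum(
    genotypes: Mapping[str, object],
    model: RiskModel,
    subject: str = "subject",
    log_base: float = math.e,
    counting: str = "copies",
) -> RiskScore:
    """Summed log odds ratios over the risk alleles a subject carries.

    ``genotypes`` maps locus id to either an (allele, allele) pair or a
    risk-allele copy count. Loci of the model missing from ``genotypes`` are
    skipped and counted in ``n_loci_missing`` (no imputation). ``counting``
    "copies" adds log OR per allele copy; "carrier" adds it once for any
    carrier (the alternative reading of a carriership model).
    """
    if counting not in ("copies", "carrier"):
        raise ValidationError(f"unknown counting mode {counting!r}")
    score = 0.0
    used = missing = 0
    for locus in model.loci:
        if locus.locus_id not in genotypes:
            missing += 1
            continue
        c = _copies(genotypes[locus.locus_id], locus)
        if counting == "carrier":
            c = min(c, 1)
        score += c * math.log(locus.odds_ratio, log_base)
        used += 1
    return RiskScore(
        subject=subject, score=score, n_loci_used=used, n_loci_missing=missing,
        subset_hash=model.subset_hash(),
    )


@dataclasses.dataclass
class CohortDistribution:
    scores: np.ndarray
    subset_hash: str
    name: str = "controls"
    log_base: float = math.e
    counting: str = "copies"

    @property
    def n(self) -> int:
        return len(self.scores)

    def summary(self) -> dict:
        return {
            "name": self.name, "n": self.n, "subset_hash": self.subset_hash,
            "mean": float(np.mean(self.scores)), "sd": float(np.std(self.scores)),
            "min": float(np.min(self.scores)), "max": float(np.max(self.scores)),
        }


def cohort_distribution(
    controls: pd.DataFrame,
    model: RiskModel,
    name: str = "controls",
    log_base: float = math.e,
    counting: str = "copies",
) -> CohortDistribution:
    """Score every control row (columns = locus ids, values = copy counts).

    The control matrix must cover exactly the model's loci; the resulting
    distribution is stamped with the locus subset hash so percentiles are
    never compared across different subsets.
    """
    model_ids = [l.locus_id for l in model.loci]
    missing = [i for i in model_ids if i not in controls.columns]
    if missing:
        raise ValidationError(f"control matrix lacks loci {missing[:5]}...")
    counts = controls[model_ids].to_numpy(dtype=float)
    if counts.size and (counts.min() < 0 or counts.max() > 2):
        raise ValidationError("control copy counts must lie in 0..2")
    if counting == "carrier":
        counts = np.minimum(counts, 1.0)
    elif counting != "copies":
        raise ValidationError(f"unknown counting mode {counting!r}")
    scores = counts @ model.log_odds(base=log_base)
    return CohortDistribution(
        scores=scores, subset_hash=model.subset_hash(), name=name,
        log_base=log_base, counting=counting,
    )


def risk_percentile(
    score: RiskScore, distribution: CohortDistribution, n_bins: int = 40
) -> tuple[RiskScore, dict]:
    """Midrank percentile of a subject's score within a control distribution.

    percentile = 100 (#controls below + ties/2) / n. Also returns histogram
    bins and the subject's vertical-line position for plotting.
    """
    if distribution.n == 0:
        raise ValidationError("empty control distribution")
    if score.subset_hash != distribution.subset_hash:
        raise ComparabilityError(
            "score and distribution were computed over different locus subsets "
            f"({score.subset_hash} vs {distribution.subset_hash})"
        )
    below = int((distribution.scores < score.score).sum())
    ties = int((distribution.scores == score.score).sum())
    pct = 100.0 * (below + 0.5 * ties) / distribution.n
    hist, edges = np.histogram(distribution.scores, bins=n_bins)
    plot_data = {
        "bin_edges": edges.tolist(),
        "counts": hist.tolist(),
        "subject_score": score.score,
        "subject": score.subject,
        "cohort": distribution.name,
    }
    return dataclasses.replace(
        score, percentile=pct, cohort_name=distribution.name
    ), plot_data


def plot_risk_histogram(plot_data: dict, path: str | None = None):
    """Control-score histogram with the subject marked as a vertical line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = plot_data["bin_edges"]
    ax.stairs(plot_data["counts"], edges, fill=True, color="#7a9cc6")
    ax.axvline(plot_data["subject_score"], color="firebrick", lw=2,
               label=plot_data.get("subject", "subject"))
    ax.set_xlabel("summed log odds ratios")
    ax.set_ylabel("controls")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
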
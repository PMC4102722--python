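"""Synthetic twin-pair data generation with planted ground truth.

The generator emulates the statistical structure the discordance analysis
assumes: co-twins share all germline variation (~0.1% nucleotide diversity by
default), substitutions follow a configurable transition/transversion spectrum
(2.1 genome-wide, 2.8 inside coding sequence), read pileups carry
phred-calibrated base errors at Poisson-distributed depth, indel-adjacent
misalignment produces spurious sample-asymmetric SNV signals, CNVs perturb
windowed depth against a background panel, and a control cohort is genotyped
at risk loci under Hardy-Weinberg equilibrium.

Every stage draws from its own pseudo-random stream derived from the master
seed and a stage label, so adding a stage never perturbs the output of
earlier ones, and a fixed seed reproduces outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SizingError, ValidationError
from .io_formats import Interval, SitePileup

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

#: the 19 bp insertion allele of the packaged misalignment fixture
ARTIFACT_INSERTION = "CGCAGCAGGGGCAGCAGGG"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream derived from the master seed."""
    return np.random.default_rng([zlib.crc32(stage.encode()), int(seed)])


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic twin-pair dataset.

    Defaults reflect the emulated design: 0.1% nucleotide diversity, Ti/Tv
    2.1 genome-wide and 2.8 in coding sequence, 40x mean depth (the genomes'
    36-48x band), Q30 bases, 58 background samples for CNV normalisation and
    a 1,920-member control cohort.
    """

    genome_length: int = 1_000_000
    diversity: float = 0.001  # heterozygous+homozygous variants per bp
    titv_genome: float = 2.1
    titv_exome: float = 2.8
    cds_fraction: float = 0.02
    mean_depth: float | Mapping[str, float] = 40.0
    base_quality_mean: int = 30
    mapping_quality_mean: int = 60
    mapping_quality_low: int = 5
    mapping_quality_low_fraction: float = 0.02
    read_length: int = 100
    het_hom_ratio: float = 2.0
    masked_fraction: float = 0.066
    n_background_samples: int = 58
    n_controls: int = 1920
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diversity", "titv_genome", "titv_exome"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.cds_fraction < 1:
            raise ValidationError("cds_fraction must lie in [0, 1)")
        if not 0 <= self.masked_fraction <= 1:
            raise ValidationError("masked_fraction must lie in [0, 1]")

    def depth_for(self, sample: str) -> float:
        if isinstance(self.mean_depth, Mapping):
            return float(self.mean_depth[sample])
        return float(self.mean_depth)


@dataclasses.dataclass(frozen=True)
class CdsInterval:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    frame: int


@dataclasses.dataclass
class ReferenceBundle:
    contigs: dict[str, str]
    gene_model: list[CdsInterval]
    masked_fraction: float = 0.0

    def cds_mask(self, contig: str) -> np.ndarray:
        mask = np.zeros(len(self.contigs[contig]), dtype=bool)
        for iv in self.gene_model:
            if iv.contig == contig:
                mask[iv.start : iv.end] = True
        return mask


@dataclasses.dataclass(frozen=True)
class GermlineVariant:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: tuple[str, str]  # identical in both co-twins
    in_cds: bool = False
    population_frequency: float | None = None


@dataclasses.dataclass(frozen=True)
class SomaticEvent:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    samples: frozenset  # affected samples, a strict subset of the design
    vaf: float


@dataclasses.dataclass(frozen=True)
class CnvEvent:
    region: Interval
    direction: str  # loss | gain
    copy_ratio: float
    samples: frozenset


@dataclasses.dataclass(frozen=True)
class ArtifactSite:
    contig: str
    pos: int
    cause: str


@dataclasses.dataclass
class TruthSet:
    germline_variants: list = dataclasses.field(default_factory=list)
    somatic_events: list = dataclasses.field(default_factory=list)
    cnv_events: list = dataclasses.field(default_factory=list)
    artifact_sites: list = dataclasses.field(default_factory=list)

    def germline_positions(self) -> set[tuple[str, int]]:
        return {(v.contig, v.pos) for v in self.germline_variants}

    def variant_positions(self) -> set[tuple[str, int]]:
        return self.germline_positions() | {
            (e.contig, e.pos) for e in self.somatic_events
        }


# ---------------------------------------------------------------------------
# reference and germline variation
# ---------------------------------------------------------------------------

def generate_reference(config: SimulationConfig, contig: str = "sim1") -> ReferenceBundle:
    """Random reference with a gene model covering ~``cds_fraction`` of it."""
    if config.genome_length < 10_000:
        raise SizingError("genome_length must be at least 10 kb")
    rng = stage_rng(config.seed, "reference")
    length = config.genome_length
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])

    gene_model: list[CdsInterval] = []
    if config.cds_fraction > 0:
        target = int(round(config.cds_fraction * length))
        lengths: list[int] = []
        total = 0
        while total < target:
            n = int(rng.integers(50, 200)) * 3  # 150-600 bp, divisible by 3
            if total + n > target:
                n = max(3, ((target - total) // 3) * 3)
            lengths.append(n)
            total += n
        free = length - total
        if free < len(lengths):
            raise SizingError(
                f"cannot place {total} bp of CDS plus gaps in {length} bp"
            )
        # distribute the free space as random gaps around the intervals
        cuts = np.sort(rng.choice(free + 1, size=len(lengths), replace=True))
        pos = 0
        prev_cut = 0
        for n, cut in zip(lengths, cuts):
            pos += int(cut) - prev_cut
            prev_cut = int(cut)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_model.append(CdsInterval(contig, pos, pos + n, strand, 0))
            pos += n
    return ReferenceBundle(
        contigs={contig: seq}, gene_model=gene_model,
        masked_fraction=config.masked_fraction,
    )


def draw_alt_alleles(
    ref_bases: Sequence[str], titv: float, rng: np.random.Generator
) -> list[str]:
    """Alternate alleles under a Ti/Tv spectrum: transition w.p. titv/(titv+1)."""
    p_ti = titv / (titv + 1.0)
    is_ti = rng.random(len(ref_bases)) < p_ti
    pick = rng.integers(0, 2, size=len(ref_bases))
    return [
        _TRANSITION_OF[b] if ti else _TRANSVERSIONS_OF[b][k]
        for b, ti, k in zip(ref_bases, is_ti, pick)
    ]


def generate_germline_variants(
    ref: ReferenceBundle, config: SimulationConfig
) -> TruthSet:
    """Shared germline SNVs for the co-twins.

    SNV count is Binomial(genome length, diversity); the exonic Ti/Tv spectrum
    applies inside CDS, the genome-wide spectrum elsewhere; heterozygotes and
    homozygotes occur at the configured het:hom ratio (default 2:1) and both
    twins receive identical genotypes.
    """
    rng = stage_rng(config.seed, "germline")
    truth = TruthSet()
    p_het = config.het_hom_ratio / (config.het_hom_ratio + 1.0)
    for contig, seq in ref.contigs.items():
        length = len(seq)
        n = int(rng.binomial(length, config.diversity)) if config.diversity > 0 else 0
        if n == 0:
            continue
        positions = np.sort(rng.choice(length, size=n, replace=False))
        cds = ref.cds_mask(contig)
        in_cds = cds[positions]
        refs = [seq[p] for p in positions]
        alts = np.empty(n, dtype="U1")
        for mask, titv in ((in_cds, config.titv_exome), (~in_cds, config.titv_genome)):
            idx = np.flatnonzero(mask)
            if idx.size:
                alts[idx] = draw_alt_alleles(
                    [refs[i] for i in idx], titv, rng
                )
        hets = rng.random(n) < p_het
        popfreq = rng.uniform(0.0, 1.0, size=n)
        for i, p in enumerate(positions):
            gt = (refs[i], str(alts[i])) if hets[i] else (str(alts[i]), str(alts[i]))
            truth.germline_variants.append(
                GermlineVariant(
                    contig=contig, pos=int(p) + 1, ref=refs[i], alt=str(alts[i]),
                    genotype=tuple(sorted(gt)), in_cds=bool(in_cds[i]),
                    population_frequency=float(popfreq[i]),
                )
            )
    return truth


def plant_somatic_events(
    truth: TruthSet, events: Iterable[SomaticEvent], all_samples: Sequence[str]
) -> TruthSet:
    """Add somatic events to a truth set, enforcing its invariants."""
    germline = truth.germline_positions()
    universe = frozenset(all_samples)
    seen = {(e.contig, e.pos) for e in truth.somatic_events}
    new = list(truth.somatic_events)
    for ev in events:
        if not 0 < ev.vaf <= 1:
            raise ValidationError(
                f"somatic event at {ev.contig}:{ev.pos} has VAF {ev.vaf} outside (0, 1]"
            )
        if (ev.contig, ev.pos) in germline:
            raise ValidationError(
                f"somatic event at {ev.contig}:{ev.pos} collides with a germline variant"
            )
        if (ev.contig, ev.pos) in seen:
            raise ValidationError(f"duplicate somatic event at {ev.contig}:{ev.pos}")
        if not ev.samples or not frozenset(ev.samples) < universe:
            raise ValidationError(
                f"somatic event at {ev.contig}:{ev.pos} must affect a non-empty "
                f"strict subset of {sorted(universe)}"
            )
        seen.add((ev.contig, ev.pos))
        new.append(ev)
    return dataclasses.replace(truth, somatic_events=new)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def _alt_probability(
    sample: str, site: tuple[str, int], germline: Mapping, somatic: Mapping
) -> tuple[str | None, float]:
    gv = germline.get(site)
    if gv is not None:
        n_alt = gv.genotype.count(gv.alt)
        return gv.alt, n_alt / 2.0
    ev = somatic.get(site)
    if ev is not None and sample in ev.samples:
        return ev.alt, ev.vaf
    return None, 0.0


def simulate_pileups(
    ref: ReferenceBundle,
    truth: TruthSet,
    config: SimulationConfig,
    samples: Sequence[str],
    positions: Iterable[tuple[str, int]] | None = None,
) -> dict[str, dict[tuple[str, int], SitePileup]]:
    """Per-sample site pileups at the requested positions.

    Positions default to every truth variant site. Depth is Poisson around the
    sample's mean; each read draws its base from the sample's local genotype
    (heterozygote 0.5, homozygote 1.0, somatic carrier its VAF) and is flipped
    to a uniformly chosen wrong base with probability 10^(-Q/10). Mapping
    qualities are bimodal: a configurable fraction of reads carries a low MQ.
    """
    if positions is None:
        positions = sorted(truth.variant_positions())
    else:
        positions = sorted(set(positions))
    germline = {(v.contig, v.pos): v for v in truth.germline_variants}
    somatic = {(e.contig, e.pos): e for e in truth.somatic_events}
    e_base = 10.0 ** (-config.base_quality_mean / 10.0)
    out: dict[str, dict[tuple[str, int], SitePileup]] = {}
    for sample in samples:
        rng = stage_rng(config.seed, f"pileup:{sample}")
        depth_mean = config.depth_for(sample)
        site_pileups: dict[tuple[str, int], SitePileup] = {}
        for contig, pos in positions:
            seq = ref.contigs[contig]
            ref_base = seq[pos - 1]
            depth = int(rng.poisson(depth_mean))
            if depth == 0:
                site_pileups[(contig, pos)] = SitePileup(
                    contig, pos, ref_base,
                    np.array([], dtype="U1"), np.array([], dtype=int),
                    np.array([], dtype=int), np.array([], dtype=int),
                    np.array([], dtype="U1"),
                )
                continue
            alt, p_alt = _alt_probability(sample, (contig, pos), germline, somatic)
            true_alt = rng.random(depth) < p_alt if alt is not None else np.zeros(depth, bool)
            bases = np.where(true_alt, alt, ref_base).astype("U1")
            # sequencing error: flip to one of the three other bases
            err = rng.random(depth) < e_base
            if err.any():
                idx = np.flatnonzero(err)
                for i in idx:
                    others = [b for b in "ACGT" if b != bases[i]]
                    bases[i] = others[rng.integers(0, 3)]
            low_mq = rng.random(depth) < config.mapping_quality_low_fraction
            mq = np.where(low_mq, config.mapping_quality_low, config.mapping_quality_mean)
            starts = pos - rng.integers(0, config.read_length, size=depth)
            strands = np.where(rng.random(depth) < 0.5, "+", "-").astype("U1")
            site_pileups[(contig, pos)] = SitePileup(
                contig, pos, ref_base, bases,
                np.full(depth, config.base_quality_mean, dtype=int),
                mq.astype(int), starts.astype(int), strands,
            )
        out[sample] = site_pileups
    return out


# ---------------------------------------------------------------------------
# indel-misalignment artifact fixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IndelArtifactFixture:
    """Synthetic two-sample fixture reproducing an indel-misalignment artifact.

    Both samples are heterozygous for a 19 bp insertion. In the *naive*
    pileups, reads of one sample that span the insertion are misaligned and
    deposit spurious mismatch bases at two nearby reference positions, so the
    samples look discordant there; the *realigned* pileups resolve the
    insertion and are artifact-free. The truth set records the two positions
    as artifact sites, not somatic events.
    """

    naive_pileups: dict
    realigned_pileups: dict
    truth: TruthSet
    insertion_allele: str
    insertion_pos: int
    contig: str
    samples: tuple[str, str]
    artifact_positions: tuple[int, int]


def generate_indel_artifact_fixture(
    seed: int = 0, depth: int = 50, contig: str = "artifact1"
) -> IndelArtifactFixture:
    rng = stage_rng(seed, "artifact")
    length = 400
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    ins_pos = 200  # insertion occurs after this 1-based position
    art_positions = (197, 204)
    samples = ("biopsy", "blood")

    def clean_pileup(pos: int, d: int) -> SitePileup:
        ref_base = seq[pos - 1]
        starts = pos - rng.integers(0, 100, size=d)
        strands = np.where(rng.random(d) < 0.5, "+", "-").astype("U1")
        return SitePileup(
            contig, pos, ref_base, np.full(d, ref_base, dtype="U1"),
            np.full(d, 30, dtype=int), np.full(d, 60, dtype=int),
            starts.astype(int), strands,
        )

    naive: dict = {s: {} for s in samples}
    realigned: dict = {s: {} for s in samples}
    for pos in art_positions:
        ref_base = seq[pos - 1]
        # spurious mismatch base contributed by misaligned insertion reads
        mismatch = next(b for b in ARTIFACT_INSERTION if b != ref_base)
        n_mis = int(round(0.4 * depth))
        bases = np.array([mismatch] * n_mis + [ref_base] * (depth - n_mis), dtype="U1")
        starts = pos - rng.integers(0, 100, size=depth)
        strands = np.where(rng.random(depth) < 0.5, "+", "-").astype("U1")
        naive["biopsy"][(contig, pos)] = SitePileup(
            contig, pos, ref_base, bases, np.full(depth, 30, dtype=int),
            np.full(depth, 60, dtype=int), starts.astype(int), strands,
        )
        naive["blood"][(contig, pos)] = clean_pileup(pos, depth)
        realigned["biopsy"][(contig, pos)] = clean_pileup(pos, depth)
        realigned["blood"][(contig, pos)] = clean_pileup(pos, depth)

    truth = TruthSet(
        artifact_sites=[
            ArtifactSite(contig, p, "indel_misalignment") for p in art_positions
        ]
    )
    return IndelArtifactFixture(
        naive_pileups=naive, realigned_pileups=realigned, truth=truth,
        insertion_allele=ARTIFACT_INSERTION, insertion_pos=ins_pos,
        contig=contig, samples=samples, artifact_positions=art_positions,
    )


# ---------------------------------------------------------------------------
# CNV depth matrices
# ---------------------------------------------------------------------------

def simulate_cnv_depth(
    config: SimulationConfig,
    cnv_events: Sequence[CnvEvent],
    samples: Sequence[str],
    n_windows: int = 2000,
    window_size: int = 100,
    contig: str = "sim1",
):
    """Windowed depth matrix for test samples plus the background panel.

    Window depth is the summed per-base coverage, drawn as
    Poisson(mean_depth x window size x copy ratio); the copy ratio is 1
    outside planted events and the event's ratio inside, for affected samples
    only. The background panel carries no events.
    """
    from .cnv import DepthMatrix

    if config.n_background_samples < 2:
        raise ValidationError("need at least 2 background samples")
    events = sorted(cnv_events, key=lambda e: (e.region.contig, e.region.start))
    for a, b in zip(events, events[1:]):
        if a.region.overlap_length(b.region) > 0:
            raise ValidationError(
                f"planted CNVs overlap: {a.region} and {b.region}"
            )
    rng = stage_rng(config.seed, "cnv-depth")
    windows = [
        Interval(contig, i * window_size, (i + 1) * window_size)
        for i in range(n_windows)
    ]
    background = [f"bg{i:03d}" for i in range(config.n_background_samples)]
    all_samples = list(samples) + background
    lam = np.empty((n_windows, len(all_samples)))
    starts = np.array([w.start for w in windows])
    for j, sample in enumerate(all_samples):
        base = config.depth_for(sample) if sample in samples else float(
            np.mean([config.depth_for(s) for s in samples])
        )
        col = np.full(n_windows, base * window_size)
        if sample in samples:
            for ev in events:
                if sample in ev.samples and ev.region.contig == contig:
                    inside = (starts >= ev.region.start) & (starts < ev.region.end)
                    col[inside] *= ev.copy_ratio
        lam[:, j] = col
    depth = rng.poisson(lam).astype(float)
    matrix = DepthMatrix(
        windows=windows, samples=all_samples, depth=depth,
        window_size=window_size, background_samples=background,
    )
    truth = TruthSet(cnv_events=list(events))
    return matrix, truth


def make_mappability_track(
    contig: str, length: int, low_regions: Sequence[Interval] = (),
    high_score: float = 1.0, low_score: float = 0.0,
) -> list[Interval]:
    """Uniqueness track: uniformly high except for the given low regions."""
    track: list[Interval] = []
    pos = 0
    for low in sorted(low_regions, key=lambda iv: iv.start):
        if low.start > pos:
            track.append(Interval(contig, pos, low.start, score=high_score))
        track.append(Interval(contig, low.start, low.end, score=low_score))
        pos = low.end
    if pos < length:
        track.append(Interval(contig, pos, length, score=high_score))
    return track


# ---------------------------------------------------------------------------
# risk-model cohort
# ---------------------------------------------------------------------------

def make_risk_model(n_loci: int = 133, seed: int = 0):
    """Synthetic stand-in for a published risk-locus table (ids, ORs, frequencies).

    Odds ratios are drawn log-normally around ~1.15 (the modest effect sizes
    typical of GWAS risk loci) and risk-allele frequencies uniformly on
    (0.05, 0.95).
    """
    from .risk import RiskLocus, RiskModel

    rng = stage_rng(seed, "risk-model")
    loci = []
    for i in range(n_loci):
        odds = float(np.exp(rng.normal(np.log(1.15), 0.12)))
        odds = max(odds, 1.01)
        freq = float(rng.uniform(0.05, 0.95))
        risk, other = rng.choice(_BASES, size=2, replace=False)
        loci.append(
            RiskLocus(
                locus_id=f"locus_{i:04d}", contig="sim1", pos=1000 * (i + 1),
                risk_allele=str(risk), other_allele=str(other),
                odds_ratio=round(odds, 4), risk_allele_freq=round(freq, 4),
            )
        )
    return RiskModel(loci)


def simulate_control_cohort(model, n: int, seed: int = 0) -> pd.DataFrame:
    """Risk-allele copy counts (0/1/2) for n controls under Hardy-Weinberg.

    Genotypes are independent across loci; locus j contributes
    Binomial(2, f_j) copies.
    """
    for locus in model.loci:
        if not 0 < locus.risk_allele_freq < 1:
            raise ValidationError(
                f"risk-allele frequency of {locus.locus_id} must lie in (0, 1)"
            )
    rng = stage_rng(seed, "controls")
    data = {
        locus.locus_id: rng.binomial(2, locus.risk_allele_freq, size=n)
        for locus in model.loci
    }
    return pd.DataFrame(data)


def simulate_twin_genotypes(
    model, seed: int = 0, freq_boost: float = 0.0
) -> dict[str, int]:
    """One subject's risk-allele copies under HWE, optionally enriched.

    ``freq_boost`` shifts every locus frequency upward (capped at 0.98),
    modelling a subject with a systematically elevated risk-allele load.
    """
    rng = stage_rng(seed, "twin-genotypes")
    return {
        locus.locus_id: int(
            rng.binomial(2, min(0.98, locus.risk_allele_freq + freq_boost))
        )
        for locus in model.loci
    }
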
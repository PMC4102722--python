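"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* pileup TSV (``#mosatwin-pileup-v1``): one row per read observation with
  columns contig, pos (1-based), ref, base, BQ, MQ, start, strand. This is the
  substrate of all per-site statistics; it deliberately replaces BAM, since the
  detectors only ever need per-site (base, quality, start, strand) tuples.
* minimal VCF v4.2 subset (via pysam): biallelic records, GT and DP honoured,
  AF read from INFO. Multi-allelic rows are rejected, not split.
* BED3+ with half-open 0-based coordinates.
* risk-model TSV, depth-matrix TSV, FASTA.

All readers reject malformed input with an error naming the line rather than
silently repairing it; every writer produces output its paired reader accepts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError, UnsupportedRecordError, ValidationError

PILEUP_MAGIC = "#mosatwin-pileup-v1"
_VALID_BASES = frozenset("ACGTN")
_REF_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SitePileup:
    """Read observations at one reference site for one sample.

    Parallel arrays hold one entry per read: called base, phred base quality,
    phred mapping quality, alignment start coordinate and strand (+/-).
    """

    contig: str
    pos: int  # 1-based
    ref_base: str
    bases: np.ndarray
    base_quals: np.ndarray
    map_quals: np.ndarray
    starts: np.ndarray
    strands: np.ndarray

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="U1")
        self.base_quals = np.asarray(self.base_quals, dtype=np.int64)
        self.map_quals = np.asarray(self.map_quals, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        if self.pos < 1:
            raise ValidationError(f"pileup position must be >= 1, got {self.pos}")
        if self.ref_base not in _REF_BASES:
            raise ValidationError(f"invalid reference base {self.ref_base!r}")
        if self.bases.size and not set(self.bases.tolist()) <= _VALID_BASES:
            bad = sorted(set(self.bases.tolist()) - _VALID_BASES)
            raise ValidationError(f"invalid observed base(s) {bad}")
        if self.base_quals.size and (self.base_quals.min() < 0 or self.map_quals.min() < 0):
            raise ValidationError("phred qualities must be >= 0")
        n = len(self.bases)
        for arr in (self.base_quals, self.map_quals, self.starts, self.strands):
            if len(arr) != n:
                raise ValidationError("pileup observation arrays must have equal length")

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    @property
    def depth(self) -> int:
        return len(self.bases)

    def allele_counts(self, alt: str, min_mq: int = 0, min_bq: int = 0) -> tuple[int, int]:
        """(ref, alt) read counts after quality filtering."""
        keep = (self.map_quals >= min_mq) & (self.base_quals >= min_bq)
        kept = self.bases[keep]
        return int((kept == self.ref_base).sum()), int((kept == alt).sum())


@dataclasses.dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotypes and depths."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict  # sample -> (allele, allele) or None for no-call
    depths: dict  # sample -> int
    population_frequency: float | None = None
    effect: str | None = None  # synonymous|missense|nonsense|non-coding

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.contig}:{self.pos}")
        alleles = {self.ref, self.alt}
        for sample, gt in self.genotypes.items():
            if gt is not None and not set(gt) <= alleles:
                raise ValidationError(
                    f"genotype {gt} of {sample} at {self.contig}:{self.pos} "
                    f"uses alleles outside {{ref, alt}}"
                )
        if self.population_frequency is not None and not 0 <= self.population_frequency <= 1:
            raise ValidationError("population_frequency must lie in [0, 1]")

    def carries_alt(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and self.alt in gt


@dataclasses.dataclass(frozen=True)
class Interval:
    """Half-open 0-based genomic interval with an optional payload."""

    contig: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Interval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup(pileups: Iterable[SitePileup], path: str | Path) -> None:
    """Write site pileups as the one-row-per-observation TSV dialect."""
    with open(path, "w") as fh:
        fh.write(PILEUP_MAGIC + "\n")
        for p in pileups:
            for b, bq, mq, st, strand in zip(
                p.bases, p.base_quals, p.map_quals, p.starts, p.strands
            ):
                fh.write(f"{p.contig}\t{p.pos}\t{p.ref_base}\t{b}\t{bq}\t{mq}\t{st}\t{strand}\n")


def read_pileup(path: str | Path) -> Iterator[SitePileup]:
    """Stream site pileups from a pileup TSV, grouped by (contig, pos).

    Raises :class:`ParseError` on malformed rows (with the line number) and on
    positions out of order within a contig. An empty file yields nothing.
    """
    rows: list[tuple] = []
    key: tuple[str, int, str] | None = None
    last_pos: dict[str, int] = {}

    def flush() -> SitePileup | None:
        if key is None:
            return None
        contig, pos, ref = key
        b, bq, mq, st, strand = zip(*rows)
        return SitePileup(contig, pos, ref, np.array(b), np.array(bq),
                          np.array(mq), np.array(st), np.array(strand))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            contig, pos_s, ref, base, bq_s, mq_s, start_s, strand = fields
            try:
                pos, bq, mq, start = int(pos_s), int(bq_s), int(mq_s), int(start_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if bq < 0 or mq < 0:
                raise ParseError(f"{path}:{lineno}: negative quality")
            if base not in _VALID_BASES or ref not in _REF_BASES:
                raise ParseError(f"{path}:{lineno}: invalid base {base!r}/{ref!r}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            site = (contig, pos, ref)
            if site != key:
                if contig in last_pos and pos <= last_pos[contig] and key is not None:
                    raise ParseError(
                        f"{path}:{lineno}: positions not sorted within contig {contig}"
                    )
                out = flush()
                if out is not None:
                    yield out
                key, rows = site, []
                last_pos[contig] = pos
            rows.append((base, bq, mq, start, strand))
    out = flush()
    if out is not None:
        yield out


# ---------------------------------------------------------------------------
# minimal VCF subset (pysam-backed)
# ---------------------------------------------------------------------------

def write_vcf_subset(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic records as an uncompressed minimal VCF v4.2."""
    header = pysam.VariantHeader()
    lengths: dict[str, int] = dict(contig_lengths or {})
    for rec in records:
        need = rec.pos + len(rec.ref)
        if lengths.get(rec.contig, 0) < need:
            lengths[rec.contig] = need
    for contig, length in lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("AF", number="A", type="Float", description="Population allele frequency")
    header.info.add("EFF", number="1", type="String", description="Coding effect class")
    header.formats.add("GT", number="1", type="String", description="Genotype")
    header.formats.add("DP", number="1", type="Integer", description="Read depth")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            row = vf.new_record(
                contig=rec.contig, start=rec.pos - 1, stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            if rec.population_frequency is not None:
                row.info["AF"] = rec.population_frequency
            if rec.effect is not None:
                row.info["EFF"] = rec.effect
            allele_index = {rec.ref: 0, rec.alt: 1}
            for s in samples:
                gt = rec.genotypes.get(s)
                row.samples[s]["GT"] = (
                    None if gt is None else tuple(allele_index[a] for a in gt)
                )
                if s in rec.depths:
                    row.samples[s]["DP"] = int(rec.depths[s])
            vf.write(row)


def read_vcf_subset(path: str | Path) -> list[VariantRecord]:
    """Read a minimal biallelic VCF; multi-allelic rows raise, unknown INFO is ignored."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise ParseError(f"{path}: FORMAT lacks GT")
        samples = list(vf.header.samples)
        for row in vf:
            if row.alts is None or len(row.alts) != 1:
                raise UnsupportedRecordError(
                    f"{path}: multi-allelic record at {row.contig}:{row.pos} is unsupported"
                )
            genotypes: dict = {}
            depths: dict = {}
            for s in samples:
                call = row.samples[s]
                gt_idx = call.get("GT")
                if gt_idx is None or any(i is None for i in gt_idx):
                    genotypes[s] = None
                else:
                    genotypes[s] = tuple(row.alleles[i] for i in gt_idx)
                dp = call.get("DP")
                if dp is not None:
                    depths[s] = int(dp)
            af = row.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            eff = row.info.get("EFF")
            out.append(
                VariantRecord(
                    contig=row.contig, pos=row.pos, ref=row.ref, alt=row.alts[0],
                    genotypes=genotypes, depths=depths,
                    population_frequency=None if af is None else float(af),
                    effect=eff,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ (optional name/score/strand) with strict validation."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                out.append(
                    Interval(
                        contig=fields[0], start=start, end=end,
                        name=fields[3] if len(fields) > 3 else None,
                        score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else None,
                        strand=fields[5] if len(fields) > 5 else None,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            extras = [iv.name, iv.score, iv.strand]
            while extras and extras[-1] is None:
                extras.pop()
            for i, x in enumerate(extras):
                if x is None:
                    x = "."
                if i == 1 and not isinstance(x, str):  # score column
                    x = f"{x:g}"
                fields.append(str(x))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# risk model TSV
# ---------------------------------------------------------------------------

def read_risk_model(path: str | Path):
    """Read a risk-model TSV (locus id, contig, pos, risk/other allele, OR, freq)."""
    from .risk import RiskLocus, RiskModel

    df = pd.read_csv(path, sep="\t", comment=None)
    required = ["locus_id", "contig", "pos", "risk_allele", "other_allele",
                "odds_ratio", "risk_allele_freq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing risk-model columns {missing}")
    if df["locus_id"].duplicated().any():
        dup = df.loc[df["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate locus id {dup!r}")
    if (df["odds_ratio"] <= 0).any():
        raise ValidationError(f"{path}: odds ratios must be > 0")
    loci = [
        RiskLocus(
            locus_id=str(r.locus_id), contig=str(r.contig), pos=int(r.pos),
            risk_allele=str(r.risk_allele), other_allele=str(r.other_allele),
            odds_ratio=float(r.odds_ratio), risk_allele_freq=float(r.risk_allele_freq),
        )
        for r in df.itertuples()
    ]
    return RiskModel(loci)


def write_risk_model(model, path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id, "contig": l.contig, "pos": l.pos,
            "risk_allele": l.risk_allele, "other_allele": l.other_allele,
            "odds_ratio": l.odds_ratio, "risk_allele_freq": l.risk_allele_freq,
        }
        for l in model.loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / depth matrix
# ---------------------------------------------------------------------------

def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_depth_matrix(matrix, path: str | Path) -> None:
    """Depth matrix as TSV: window coordinates then one column per sample."""
    df = pd.DataFrame(matrix.depth, columns=matrix.samples)
    df.insert(0, "end", [w.end for w in matrix.windows])
    df.insert(0, "start", [w.start for w in matrix.windows])
    df.insert(0, "contig", [w.contig for w in matrix.windows])
    df.to_csv(path, sep="\t", index=False)


def read_depth_matrix(path: str | Path):
    from .cnv import DepthMatrix

    df = pd.read_csv(path, sep="\t")
    for col in ("contig", "start", "end"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing depth-matrix column {col!r}")
    windows = [
        Interval(c, int(s), int(e))
        for c, s, e in zip(df["contig"], df["start"], df["end"])
    ]
    samples = [c for c in df.columns if c not in ("contig", "start", "end")]
    depth = df[samples].to_numpy(dtype=float)
    sizes = {len(w) for w in windows}
    window_size = sizes.pop() if len(sizes) == 1 else None
    return DepthMatrix(windows=windows, samples=samples, depth=depth,
                       window_size=window_size)
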
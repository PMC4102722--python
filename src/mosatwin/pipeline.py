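"""End-to-end orchestration: simulate -> genotype -> somatic -> cnv -> risk -> report.

The pipeline runs the full twin-pair analysis on a synthetic dataset with
planted truth and emits a machine-readable report whose every count is
reproducible from the written artifacts. Reruns with the same configuration
produce identical reports: all randomness flows from the master seed through
labelled per-stage streams and floats are serialized at fixed precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import cnv as cnvmod
from . import io_formats as io
from . import risk as riskmod
from . import simulate as sim
from . import somatic as som
from .errors import ConfigError
from .genotyping import genotype_likelihoods, pairwise_concordance

log = logging.getLogger("mosatwin")

FOUR_SAMPLE_ROLES = som.SAMPLE_ROLES
TWO_SAMPLE_ROLES = ("affected_blood", "healthy_blood")


@dataclasses.dataclass
class PipelineConfig:
    """Validated run configuration (see configs written by ``demo``)."""

    design: str = "four_sample"  # or "two_sample"
    samples: dict = dataclasses.field(
        default_factory=lambda: {
            "affected_blood": "cd_blood", "affected_biopsy": "cd_biopsy",
            "healthy_blood": "he_blood", "healthy_biopsy": "he_biopsy",
        }
    )
    seed: int = 0
    genome_length: int = 1_000_000
    diversity: float = 0.001
    mean_depth: float = 40.0
    n_somatic_tissue: int = 5  # planted in the affected biopsy only
    n_somatic_twin: int = 5  # planted in both samples of the affected twin
    somatic_vaf: float = 0.5
    n_cnv_events: int = 2
    cnv_event_windows: int = 30
    cnv_total_windows: int = 2000
    n_risk_loci: int = 133
    risk_freq_boost: float = 0.2
    outdir: str = "mosatwin_out"
    max_popfreq: float = 0.20
    top_k: int = 100

    def __post_init__(self) -> None:
        roles = FOUR_SAMPLE_ROLES if self.design == "four_sample" else TWO_SAMPLE_ROLES
        if self.design not in ("four_sample", "two_sample"):
            raise ConfigError(f"unknown design {self.design!r}")
        missing = [r for r in roles if r not in self.samples]
        if missing:
            raise ConfigError(f"design {self.design} requires sample roles {missing}")
        unknown = [r for r in self.samples if r not in FOUR_SAMPLE_ROLES]
        if unknown:
            raise ConfigError(f"unknown sample role(s) {unknown}")
        labels = [self.samples[r] for r in roles]
        if len(set(labels)) != len(labels):
            raise ConfigError("sample labels must be unique")

    @property
    def roles(self) -> tuple[str, ...]:
        return FOUR_SAMPLE_ROLES if self.design == "four_sample" else TWO_SAMPLE_ROLES

    @property
    def sample_labels(self) -> list[str]:
        return [self.samples[r] for r in self.roles]

    def sim_config(self) -> sim.SimulationConfig:
        return sim.SimulationConfig(
            genome_length=self.genome_length, diversity=self.diversity,
            mean_depth=self.mean_depth, seed=self.seed,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = [k for k in d if k not in known]
        if unknown:
            raise ConfigError(f"unknown configuration key(s) {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def comparison_plan(config: PipelineConfig) -> list[tuple[str, str]]:
    """The pairwise comparisons of the study design (test, reference)."""
    s = config.samples
    if config.design == "four_sample":
        return [
            (s["affected_biopsy"], s["affected_blood"]),
            (s["affected_blood"], s["healthy_blood"]),
            (s["affected_biopsy"], s["healthy_biopsy"]),
        ]
    return [(s["affected_blood"], s["healthy_blood"])]


def veto_map(config: PipelineConfig) -> dict[tuple[str, str], list[str]]:
    """Held-out samples whose carrying the allele vetoes a candidate.

    A genuine somatic difference must be absent from the healthy twin
    entirely; for the within-twin tissue comparison both healthy samples are
    informative, for the cross-twin comparisons the healthy twin's other
    tissue is.
    """
    if config.design != "four_sample":
        return {}
    s = config.samples
    return {
        (s["affected_biopsy"], s["affected_blood"]): [
            s["healthy_blood"], s["healthy_biopsy"]],
        (s["affected_blood"], s["healthy_blood"]): [s["healthy_biopsy"]],
        (s["affected_biopsy"], s["healthy_biopsy"]): [s["healthy_blood"]],
    }


# ---------------------------------------------------------------------------
# simulation of one dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TwinDataset:
    config: PipelineConfig
    reference: sim.ReferenceBundle
    truth: sim.TruthSet
    pileups: dict  # sample -> site -> SitePileup


def plant_events_for_design(
    config: PipelineConfig, ref: sim.ReferenceBundle, truth: sim.TruthSet
) -> sim.TruthSet:
    """Choose somatic positions away from germline sites and plant them."""
    rng = sim.stage_rng(config.seed, "plant")
    contig = next(iter(ref.contigs))
    seq = ref.contigs[contig]
    germline = truth.germline_positions()
    s = config.samples
    subsets: list[frozenset] = []
    if config.design == "four_sample":
        subsets += [frozenset([s["affected_biopsy"]])] * config.n_somatic_tissue
        subsets += [
            frozenset([s["affected_blood"], s["affected_biopsy"]])
        ] * config.n_somatic_twin
    else:
        subsets += [frozenset([s["affected_blood"]])] * (
            config.n_somatic_tissue + config.n_somatic_twin
        )
    events = []
    taken = set(germline)
    for subset in subsets:
        while True:
            pos = int(rng.integers(1, len(seq) + 1))
            if (contig, pos) not in taken:
                break
        taken.add((contig, pos))
        ref_base = seq[pos - 1]
        alt = sim.draw_alt_alleles([ref_base], 2.1, rng)[0]
        events.append(sim.SomaticEvent(contig, pos, ref_base, alt, subset,
                                       config.somatic_vaf))
    return sim.plant_somatic_events(truth, events, config.sample_labels)


def simulate_dataset(config: PipelineConfig) -> TwinDataset:
    sc = config.sim_config()
    ref = sim.generate_reference(sc)
    truth = sim.generate_germline_variants(ref, sc)
    truth = plant_events_for_design(config, ref, truth)
    pileups = sim.simulate_pileups(ref, truth, sc, config.sample_labels)
    return TwinDataset(config=config, reference=ref, truth=truth, pileups=pileups)


def call_genotypes(dataset: TwinDataset) -> dict:
    """Genotype every sample at every truth site: sample -> site -> call."""
    return {
        sample: {
            site: genotype_likelihoods(p)
            for site, p in sites.items()
        }
        for sample, sites in dataset.pileups.items()
    }


def build_callset(dataset: TwinDataset, calls: Mapping) -> list[io.VariantRecord]:
    """VariantRecords over truth sites from the genotype calls."""
    germline = {(v.contig, v.pos): v for v in dataset.truth.germline_variants}
    somatic = {(e.contig, e.pos): e for e in dataset.truth.somatic_events}
    samples = dataset.config.sample_labels
    records: list[io.VariantRecord] = []
    for site in sorted(dataset.truth.variant_positions()):
        contig, pos = site
        if site in germline:
            v = germline[site]
            ref, alt, popfreq = v.ref, v.alt, v.population_frequency
        else:
            e = somatic[site]
            ref, alt, popfreq = e.ref, e.alt, None
        genotypes = {}
        depths = {}
        for s in samples:
            call = calls[s].get(site)
            if call is None:
                genotypes[s] = None
                continue
            depths[s] = call.depth
            gt = call.genotype
            genotypes[s] = gt if set(gt) <= {ref, alt} else None
        records.append(io.VariantRecord(
            contig=contig, pos=pos, ref=ref, alt=alt, genotypes=genotypes,
            depths=depths, population_frequency=popfreq,
        ))
    return records


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_somatic_stage(dataset: TwinDataset, callset: Sequence[io.VariantRecord]):
    config = dataset.config
    if config.design == "four_sample":
        roles = {r: config.samples[r] for r in FOUR_SAMPLE_ROLES}
        query = som.select_query_positions(callset, roles, config.max_popfreq)
    else:
        log.info("somatic: two-sample design, query-position reduction "
                 "not applicable; using all variant sites")
        query = [(r.contig, r.pos) for r in callset]
    plan = comparison_plan(config)
    thresholds = som.DetectorThresholds()
    calls = som.detect_discordances(dataset.pileups, plan, thresholds, sites=query)
    candidates = [c for c in calls if c.passes_threshold]
    arbitrated = som.arbitrate_with_realignment(
        candidates, dataset.pileups, dataset.pileups,  # no realignment artifacts planted
        thresholds=thresholds, veto_map=veto_map(config),
    )
    venn = som.method_overlap({
        d: som.top_k(calls, d, config.top_k)
        for d in ("score", "fisher", "filtered_fisher")
    })
    evaluation = som.evaluate_against_truth(arbitrated, dataset.truth)
    return {
        "query_positions": query, "calls": calls, "candidates": candidates,
        "arbitrated": arbitrated, "venn": venn, "evaluation": evaluation,
        "n_tests": len(calls),
    }


def plant_cnv_events(config: PipelineConfig) -> list[sim.CnvEvent]:
    window = 100
    events = []
    s = config.samples
    affected = (
        [s["affected_blood"], s["affected_biopsy"]]
        if config.design == "four_sample" else [s["affected_blood"]]
    )
    for i in range(config.n_cnv_events):
        start_w = 200 + i * (config.cnv_event_windows + 200)
        region = io.Interval(
            "sim1", start_w * window, (start_w + config.cnv_event_windows) * window
        )
        direction = "loss" if i % 2 == 0 else "gain"
        ratio = 0.5 if direction == "loss" else 1.5
        events.append(sim.CnvEvent(region, direction, ratio, frozenset(affected)))
    return events


def run_cnv_stage(config: PipelineConfig, genotype_calls: Mapping | None = None):
    events = plant_cnv_events(config)
    matrix, cnv_truth = sim.simulate_cnv_depth(
        config.sim_config(), events, config.sample_labels,
        n_windows=config.cnv_total_windows,
    )
    ratios = cnvmod.normalize_depth(matrix)
    params = cnvmod.CnvParams()
    regions = {
        s: cnvmod.call_cnv_regions(ratios[s], matrix.windows, s, params)
        for s in config.sample_labels
    }
    result = {"matrix": matrix, "truth": cnv_truth, "regions": regions}
    if config.design == "four_sample":
        s = config.samples
        track = sim.make_mappability_track("sim1", config.cnv_total_windows * 100)
        cascade = cnvmod.differential_cnv_filter(
            (regions[s["affected_blood"]], regions[s["affected_biopsy"]]),
            (regions[s["healthy_blood"]], regions[s["healthy_biopsy"]]),
            track, params,
        )
        result["cascade"] = cascade
        if genotype_calls is not None:
            loh = {}
            for i, cand in enumerate(cascade.candidates):
                if cand.direction != "loss":
                    continue
                loh[f"candidate_{i}"] = cnvmod.loh_support(
                    cand.interval,
                    genotype_calls[s["affected_blood"]],
                    genotype_calls[s["healthy_blood"]],
                )
            result["loh"] = loh
    else:
        log.info("cnv: two-sample design, twin-differential cascade skipped")
    return result


def run_risk_stage(config: PipelineConfig):
    model = sim.make_risk_model(config.n_risk_loci, seed=config.seed)
    controls = sim.simulate_control_cohort(model, config.sim_config().n_controls,
                                           seed=config.seed)
    dist = riskmod.cohort_distribution(controls, model)
    twin = sim.simulate_twin_genotypes(model, seed=config.seed,
                                       freq_boost=config.risk_freq_boost)
    score = riskmod.risk_sum(twin, model, subject="twin_pair")
    score, plot_data = riskmod.risk_percentile(score, dist)
    return {"model": model, "distribution": dist, "score": score,
            "plot_data": plot_data}


# ---------------------------------------------------------------------------
# report and entry point
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_candidates_tsv(calls, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "contig": c.contig, "pos": c.pos, "test": c.test_sample,
            "ref": c.ref_sample, "detector": c.detector,
            "statistic": round(c.statistic, 6), "passes": c.passes_threshold,
            "alt": c.alt or ".", "arbitration": c.arbitration,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["contig", "pos", "test", "ref", "detector", "statistic",
                       "passes", "alt", "arbitration"],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts plus a machine-readable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("simulate: %s design, seed %d", config.design, config.seed)
    dataset = simulate_dataset(config)
    io.write_fasta(dataset.reference.contigs, outdir / "reference.fa")

    log.info("genotype: %d sites x %d samples",
             len(dataset.truth.variant_positions()), len(config.sample_labels))
    calls = call_genotypes(dataset)
    callset = build_callset(dataset, calls)
    io.write_vcf_subset(
        callset, outdir / "calls.vcf", config.sample_labels,
        contig_lengths={c: len(s) for c, s in dataset.reference.contigs.items()},
    )
    s = config.samples
    concordance = pairwise_concordance(
        calls[s["affected_blood"]], calls[s["healthy_blood"]]
    )

    log.info("somatic: running detectors")
    somatic_res = run_somatic_stage(dataset, callset)
    _write_candidates_tsv(somatic_res["arbitrated"], outdir / "candidates.tsv")
    with open(outdir / "venn.json", "w") as fh:
        json.dump(somatic_res["venn"], fh, indent=1, sort_keys=True)

    log.info("cnv: depth simulation and cascade")
    cnv_res = run_cnv_stage(config, genotype_calls=calls)
    io.write_depth_matrix(cnv_res["matrix"], outdir / "depth_matrix.tsv")
    cascade = cnv_res.get("cascade")
    if cascade is not None:
        io.write_bed(
            [dataclasses.replace(c.interval, name=c.direction)
             for c in cascade.candidates],
            outdir / "cnv_candidates.bed",
        )

    log.info("risk: scoring against simulated control cohort")
    risk_res = run_risk_stage(config)
    with open(outdir / "risk_distribution.json", "w") as fh:
        json.dump(_round_floats({
            "summary": risk_res["distribution"].summary(),
            "plot": risk_res["plot_data"],
        }), fh, indent=1, sort_keys=True)

    ev = somatic_res["evaluation"]
    verdicts: dict = {}
    for c in somatic_res["arbitrated"]:
        verdicts[c.arbitration] = verdicts.get(c.arbitration, 0) + 1
    report = {
        "config": dataclasses.asdict(config),
        "counts": {
            "germline_variants": len(dataset.truth.germline_variants),
            "somatic_planted": len(dataset.truth.somatic_events),
            "query_positions": len(somatic_res["query_positions"]),
            "detector_tests": somatic_res["n_tests"],
            "candidates_passing": len(somatic_res["candidates"]),
            "arbitration": verdicts,
            "venn": somatic_res["venn"],
            "cnv_regions_per_sample": {
                k: len(v) for k, v in cnv_res["regions"].items()
            },
            "cnv_cascade": cascade.audit if cascade is not None else None,
        },
        "qc": {
            "twin_blood_concordance": concordance.fraction,
            "n_concordance_sites": concordance.n_compared,
        },
        "truth_evaluation": {
            "sensitivity": ev.sensitivity,
            "n_planted": ev.n_planted,
            "n_recovered": ev.n_recovered,
            "false_discoveries": ev.false_discoveries,
        },
        "risk": {
            "score": risk_res["score"].score,
            "percentile": risk_res["score"].percentile,
            "n_loci_used": risk_res["score"].n_loci_used,
            "control_mean": float(np.mean(risk_res["distribution"].scores)),
            "expected_control_mean": risk_res["model"].expected_control_mean(),
        },
    }
    report = _round_floats(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    report["digests"] = {
        p.name: _digest(p) for p in sorted(outdir.iterdir()) if p.is_file()
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("report written to %s", outdir / "report.json")
    return report


def make_demo_dataset(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write demo configurations: a four-sample design, a two-sample design
    and the packaged indel-misalignment fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    four = PipelineConfig(design="four_sample", seed=seed,
                          outdir=str(outdir / "four_sample"))
    two = PipelineConfig(
        design="two_sample",
        samples={"affected_blood": "cd_blood", "healthy_blood": "he_blood"},
        seed=seed, outdir=str(outdir / "two_sample"),
    )
    for name, cfg in (("four_sample", four), ("two_sample", two)):
        path = outdir / f"{name}.yaml"
        cfg.to_yaml(path)
        paths[name] = path
    fixture = sim.generate_indel_artifact_fixture(seed)
    for kind, pset in (("naive", fixture.naive_pileups),
                       ("realigned", fixture.realigned_pileups)):
        for sample, sites in pset.items():
            path = outdir / f"artifact_{kind}_{sample}.pileup.tsv"
            io.write_pileup([sites[k] for k in sorted(sites)], path)
            paths[f"artifact_{kind}_{sample}"] = path
    return paths
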
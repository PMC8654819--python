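"""End-to-end nomination pipeline.

Stage order is fixed: quality -> flags -> deletion (the pair filters) ->
coverage -> peaks -> control subtraction per replicate -> replicate
intersection -> log10 ranking -> protospacer annotation.  Two independent
replicate experiments are the default; more are folded in by iterated
pairwise intersection, which the min-height rule makes associative.

`nominate_replicates` is the in-memory core; `run_pipeline` wraps it (or
SAM-file inputs) with persistence of every intermediate plus a
machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .annotate import CandidateSite, find_protospacer, label_on_target
from .genome import ReferenceGenome, SgRNASpec
from .peaks import (CoverageTrack, Peak, call_peaks, coverage,
                    intersect_replicates, peaks_to_bedgraph, rank_sites,
                    subtract_control)
from .samfilter import (FilterReport, ReadPairRecord, filter_pairs,
                        read_sam_pairs, write_sam)
from .simulate import (PlantedSite, SimParams, make_genome, plant_sites,
                       simulate_negative_control, simulate_reads)

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    min_mean_q: float = 20.0
    max_deletion: int = 20
    deletion_metric: str = "max"


@dataclass
class PeakParams:
    min_height: int = 1
    merge_gap: int = 0


@dataclass
class AnnotParams:
    flank: int = 25
    tolerance: int = 5


@dataclass
class SimulateBlock:
    """Config for a fully simulated run."""

    n_contigs: int = 1
    contig_length: int = 50_000
    mismatch_counts: list[int] = field(default_factory=lambda: [0])
    cleave_probs: list[float] | None = None
    replicates: int = 2
    params: SimParams = field(default_factory=SimParams)


@dataclass
class ReplicateInput:
    """SAM-file inputs for one replicate experiment."""

    sample_sam: str
    control_sam: str | None = None


@dataclass
class RunConfig:
    outdir: str
    sgrna: SgRNASpec
    seed: int = 0
    simulate: SimulateBlock | None = None
    genome_fasta: str | None = None
    inputs: list[ReplicateInput] = field(default_factory=list)
    on_target: tuple[str, int] | None = None  # truth cut, for labelling
    filter: FilterParams = field(default_factory=FilterParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    annotate: AnnotParams = field(default_factory=AnnotParams)
    top_n: int | None = None
    force: bool = False

    def __post_init__(self) -> None:
        if self.filter.min_mean_q <= 0 or self.filter.max_deletion <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs a simulate block or SAM inputs")
        n_reps = (self.simulate.replicates if self.simulate
                  else len(self.inputs))
        if n_reps < 1:
            raise ValueError("at least one replicate is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("on_target"):
            d["on_target"] = list(d["on_target"])
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["sgrna"] = SgRNASpec(**d["sgrna"])
        if d.get("simulate"):
            sim = dict(d["simulate"])
            sim["params"] = SimParams(**sim.get("params", {}))
            d["simulate"] = SimulateBlock(**sim)
        d["inputs"] = [ReplicateInput(**r) for r in d.get("inputs", [])]
        if d.get("on_target"):
            d["on_target"] = (d["on_target"][0], int(d["on_target"][1]))
        for key, klass in (("filter", FilterParams), ("peaks", PeakParams),
                           ("annotate", AnnotParams)):
            if d.get(key):
                d[key] = klass(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ReplicateResult:
    sample_report: FilterReport
    control_report: FilterReport | None
    sample_track: CoverageTrack
    sample_peaks: list[Peak]
    control_peaks: list[Peak]
    surviving_peaks: list[Peak]
    kept_pairs: list[ReadPairRecord] = field(default_factory=list)


@dataclass
class RunResult:
    table: pd.DataFrame  # ranked, annotated candidates
    common_peaks: list[Peak]
    replicates: list[ReplicateResult]
    candidates: list[CandidateSite]
    genome: ReferenceGenome | None = None
    truth_sites: list[PlantedSite] = field(default_factory=list)


def _derive_seed(base: int, replicate: int, which: int) -> int:
    """Deterministic per-replicate stream seed, kept below 2**31."""
    return (base * 1_000 + replicate * 10 + which) % (2**31 - 1)


def process_replicate(
    sample_pairs: Sequence[ReadPairRecord],
    control_pairs: Sequence[ReadPairRecord] | None,
    contig_lengths: dict[str, int],
    fparams: FilterParams,
    pparams: PeakParams,
) -> ReplicateResult:
    """Filter -> coverage -> peaks -> control subtraction for one replicate."""
    kept, report = filter_pairs(
        sample_pairs, fparams.min_mean_q, fparams.max_deletion,
        fparams.deletion_metric)
    track = coverage(kept, contig_lengths)
    sample_peaks = call_peaks(track, pparams.min_height, pparams.merge_gap)
    if control_pairs is None:
        warnings.warn(
            "no negative control supplied: control subtraction SKIPPED; "
            "artifact peaks will not be removed", stacklevel=2)
        logger.warning("control subtraction skipped (no control input)")
        return ReplicateResult(report, None, track, sample_peaks, [],
                               list(sample_peaks), kept)
    ctrl_kept, ctrl_report = filter_pairs(
        control_pairs, fparams.min_mean_q, fparams.max_deletion,
        fparams.deletion_metric)
    ctrl_track = coverage(ctrl_kept, contig_lengths)
    control_peaks = call_peaks(ctrl_track, pparams.min_height,
                               pparams.merge_gap)
    surviving = subtract_control(sample_peaks, control_peaks)
    return ReplicateResult(report, ctrl_report, track, sample_peaks,
                           control_peaks, surviving, kept)


def annotate_ranked(
    ranked: pd.DataFrame,
    common_peaks: Sequence[Peak],
    genome: ReferenceGenome,
    sgrna: SgRNASpec,
    aparams: AnnotParams,
    on_target: tuple[str, int] | None = None,
) -> tuple[pd.DataFrame, list[CandidateSite]]:
    """Attach protospacer annotation columns to the ranked peak table."""
    by_key = {(p.contig, p.start, p.end): p for p in common_peaks}
    candidates: list[CandidateSite | None] = []
    for _, row in ranked.iterrows():
        peak = by_key[(row["contig"], row["start"], row["end"])]
        site = find_protospacer(genome, peak, sgrna, aparams.flank)
        if site is not None and on_target is not None:
            site = label_on_target(site, on_target, aparams.tolerance)
        candidates.append(site)
    table = ranked.copy()
    table["protospacer"] = [
        c.matched_protospacer if c else "." for c in candidates]
    table["strand"] = [c.match_strand if c else "." for c in candidates]
    table["mismatches"] = [c.mismatches if c else -1 for c in candidates]
    table["pam"] = [c.pam_observed if c else "." for c in candidates]
    table["cut_pos"] = [c.cut_pos if c else -1 for c in candidates]
    table["is_on_target"] = [bool(c.is_on_target) if c else False
                             for c in candidates]
    return table, [c for c in candidates if c is not None]


def nominate_replicates(
    genome: ReferenceGenome,
    replicate_pairs: Sequence[tuple[Sequence[ReadPairRecord],
                                    Sequence[ReadPairRecord] | None]],
    sgrna: SgRNASpec,
    fparams: FilterParams | None = None,
    pparams: PeakParams | None = None,
    aparams: AnnotParams | None = None,
    on_target: tuple[str, int] | None = None,
) -> RunResult:
    """In-memory nomination over >= 1 replicate (sample, control) streams."""
    fparams = fparams or FilterParams()
    pparams = pparams or PeakParams()
    aparams = aparams or AnnotParams()
    lengths = genome.lengths
    reps = [
        process_replicate(sample, control, lengths, fparams, pparams)
        for sample, control in replicate_pairs
    ]
    common = reps[0].surviving_peaks
    for rep in reps[1:]:
        common = intersect_replicates(common, rep.surviving_peaks)
    ranked = rank_sites(common)
    table, candidates = annotate_ranked(ranked, common, genome, sgrna,
                                        aparams, on_target)
    return RunResult(table, common, reps, candidates, genome=genome)


def simulate_experiment(
    config: RunConfig,
) -> tuple[ReferenceGenome, list[PlantedSite], list[tuple], list]:
    """Build genome + truth sites and simulate every replicate library."""
    sim = config.simulate
    assert sim is not None
    genome = make_genome(config.seed, sim.n_contigs, sim.contig_length)
    genome, sites = plant_sites(
        genome, config.sgrna, sim.mismatch_counts, sim.cleave_probs,
        seed=_derive_seed(config.seed, 0, 9),
        min_separation=2 * sim.params.fragment_length_mean)
    replicate_pairs = []
    sim_outputs = []
    for r in range(sim.replicates):
        sp = dataclasses.replace(sim.params,
                                 seed=_derive_seed(config.seed, r, 1))
        cp = dataclasses.replace(sim.params,
                                 seed=_derive_seed(config.seed, r, 1))
        sample = simulate_reads(genome, sites, sp, exclude_sites=sites)
        control = simulate_negative_control(genome, cp, exclude_sites=sites)
        replicate_pairs.append((sample.pairs, control.pairs))
        sim_outputs.append((sample, control))
    return genome, sites, replicate_pairs, sim_outputs


def run_pipeline(config: RunConfig, persist: bool = True) -> RunResult:
    """Execute the full pipeline described by `config`.

    With `persist=True` every intermediate and the final report are
    written under `config.outdir`; an existing outdir is refused unless
    `config.force` is set.  Outputs are byte-identical for identical
    config + seed.
    """
    t0 = time.monotonic()
    if persist:
        if os.path.exists(config.outdir) and os.listdir(config.outdir):
            if not config.force:
                raise FileExistsError(
                    f"output directory {config.outdir} exists; "
                    "use force=True/--force to overwrite")
        os.makedirs(config.outdir, exist_ok=True)
        # fail before any stage runs if the outdir is unwritable
        probe = os.path.join(config.outdir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)

    truth_sites: list[PlantedSite] = []
    sim_outputs: list = []
    if config.simulate is not None:
        genome, truth_sites, replicate_pairs, sim_outputs = \
            simulate_experiment(config)
        on_target = config.on_target
        if on_target is None and truth_sites:
            on_t = min(truth_sites, key=lambda s: s.mismatches)
            on_target = (on_t.contig, on_t.cut_pos)
    else:
        if not config.genome_fasta:
            raise ValueError("genome_fasta is required for SAM-file inputs")
        genome = ReferenceGenome.from_fasta(config.genome_fasta)
        replicate_pairs = [
            (list(read_sam_pairs(rep.sample_sam)),
             list(read_sam_pairs(rep.control_sam)) if rep.control_sam
             else None)
            for rep in config.inputs
        ]
        on_target = config.on_target

    result = nominate_replicates(
        genome, replicate_pairs, config.sgrna, config.filter, config.peaks,
        config.annotate, on_target)
    result.truth_sites = truth_sites
    if config.top_n is not None:
        result.table = result.table.head(config.top_n)

    if persist:
        _persist(config, genome, result, sim_outputs,
                 elapsed=time.monotonic() - t0)
    return result


def _persist(config: RunConfig, genome: ReferenceGenome, result: RunResult,
             sim_outputs: list, elapsed: float) -> None:
    out = config.outdir
    join = os.path.join
    genome.to_fasta(join(out, "genome.fa"))
    for r, ((sample, control)) in enumerate(sim_outputs):
        with open(join(out, f"sample_r{r}.R1.fastq"), "w") as fh:
            fh.write(sample.fastq_r1)
        with open(join(out, f"sample_r{r}.R2.fastq"), "w") as fh:
            fh.write(sample.fastq_r2)
        with open(join(out, f"sample_r{r}.truth.sam"), "w") as fh:
            fh.write(sample.truth_sam)
        with open(join(out, f"control_r{r}.truth.sam"), "w") as fh:
            fh.write(control.truth_sam)
    if result.truth_sites:
        with open(join(out, "truth_sites.bed"), "w") as fh:
            for site in result.truth_sites:
                fh.write(site.to_bed6() + "\n")
    for r, rep in enumerate(result.replicates):
        write_sam(rep.kept_pairs, genome.lengths,
                  join(out, f"sample_r{r}.kept.sam"))
        with open(join(out, f"sample_r{r}.filter_report.tsv"), "w") as fh:
            fh.write(rep.sample_report.to_tsv())
        with open(join(out, f"sample_r{r}.coverage.bedGraph"), "w") as fh:
            fh.write(rep.sample_track.to_bedgraph())
        with open(join(out, f"sample_r{r}.peaks.bedGraph"), "w") as fh:
            fh.write(peaks_to_bedgraph(rep.sample_peaks))
        with open(join(out, f"sample_r{r}.subtracted.bedGraph"), "w") as fh:
            fh.write(peaks_to_bedgraph(rep.surviving_peaks))
    with open(join(out, "peaks.bedGraph"), "w") as fh:
        fh.write(peaks_to_bedgraph(result.common_peaks))
    result.table.to_csv(join(out, "ranked_candidates.tsv"), sep="\t",
                        index=False)
    write_report(config, result, join(out, "report.json"))
    with open(join(out, "run.log"), "w") as fh:
        fh.write(f"elapsed_seconds\t{elapsed:.3f}\n")
        for key, value in sorted(_flatten(config.to_dict()).items()):
            fh.write(f"param\t{key}\t{value}\n")


def write_report(config: RunConfig, result: RunResult, path: str) -> None:
    """Machine-readable run report: filter accounting, per-stage peak
    counts, and the top candidate table."""
    reps = []
    for rep in result.replicates:
        reps.append({
            "filter": dataclasses.asdict(rep.sample_report),
            "control_filter": (dataclasses.asdict(rep.control_report)
                               if rep.control_report else None),
            "sample_peaks": len(rep.sample_peaks),
            "control_peaks": len(rep.control_peaks),
            "surviving_peaks": len(rep.surviving_peaks),
        })
    # the config echo omits run-location fields so identical analyses
    # written to different directories produce identical reports
    config_echo = {k: v for k, v in config.to_dict().items()
                   if k not in ("outdir", "force")}
    report = {
        "config": config_echo,
        "replicates": reps,
        "common_peaks": len(result.common_peaks),
        "candidates": result.table.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Default simulation study: the package's reference conditions for
# end-to-end verification.  One 50 kb contig; an on-target site with
# cleavage probability 1.0 and eight off-targets carrying 1-6 spacer
# mismatches with probabilities 0.85 down to 0.10; 200 pairs of depth per
# site; two replicate experiments, each with its own negative control and
# shared artifact loci.

DEFAULT_STUDY_SPACER = "GAGTCCGAGCAGAAGAAGAA"
DEFAULT_STUDY_MISMATCHES = [0, 1, 1, 2, 2, 3, 4, 5, 6]
DEFAULT_STUDY_CLEAVE_PROBS = [
    1.0, 0.85, 0.7428571428571429, 0.6357142857142857, 0.5285714285714286,
    0.42142857142857143, 0.3142857142857143, 0.20714285714285716, 0.1,
]


def default_study_config(seed: int, outdir: str = "study_out") -> RunConfig:
    """RunConfig for the default simulation study at the given seed."""
    return RunConfig(
        outdir=outdir,
        sgrna=SgRNASpec(DEFAULT_STUDY_SPACER),
        seed=seed,
        simulate=SimulateBlock(
            n_contigs=1,
            contig_length=50_000,
            mismatch_counts=list(DEFAULT_STUDY_MISMATCHES),
            cleave_probs=list(DEFAULT_STUDY_CLEAVE_PROBS),
            replicates=2,
            params=SimParams(depth_per_site=200),
        ),
    )


def run_default_study(seed: int) -> dict:
    """One in-memory run of the default study, with truth bookkeeping.

    Returns a summary dict: whether the top-ranked annotated site is the
    on-target, which planted sites were recovered by a surviving common
    peak, and how many surviving peaks trace to artifact-only loci.
    """
    cfg = default_study_config(seed)
    genome, sites, replicate_pairs, sim_outputs = simulate_experiment(cfg)
    on_t = sites[0]
    result = nominate_replicates(
        genome, replicate_pairs, cfg.sgrna, cfg.filter, cfg.peaks,
        cfg.annotate, on_target=(on_t.contig, on_t.cut_pos))
    table = result.table

    def covers(peak_row, contig, pos):
        return (peak_row["contig"] == contig
                and peak_row["start"] <= pos < peak_row["end"])

    recovered = {
        s.name: any(covers(row, s.contig, s.cut_pos)
                    for _, row in table.iterrows())
        for s in sites
    }
    artifact_loci = {loc for sample, _ in sim_outputs
                     for loc in sample.artifact_loci}
    site_hits = {
        i for s in sites for i, row in table.iterrows()
        if covers(row, s.contig, s.cut_pos)
    }
    artifact_survivors = sum(
        1 for i, row in table.iterrows()
        if i not in site_hits
        and any(covers(row, c, p) for c, p in artifact_loci)
    )
    top1_on_target = bool(len(table) and table.iloc[0]["is_on_target"])
    return {
        "top1_on_target": top1_on_target,
        "recovered": recovered,
        "cleave_probs": {s.name: s.cleave_prob for s in sites},
        "artifact_survivors": artifact_survivors,
        "n_candidates": int(len(table)),
        "n_artifact_loci": len(artifact_loci),
    }


def _plain(obj):
    """Recursively convert numpy scalars so YAML/JSON can serialize."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        return obj.item()
    return obj


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out
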
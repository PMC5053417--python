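"""End-to-end orchestration: seeded benchmark runs and consolidated reports.

``run_benchmark`` wires the whole pipeline together on synthetic data:
generate an accession pair with a known divergence ledger, simulate reads
for both accessions, run the reciprocal ZCR/PAV analysis, and score the
calls against the truth registry (recall, false calls, direction labels,
boundary accuracy, size-bin tables).  One global seed fans out to
per-stage seeds through a counter-based derivation so stages stay
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import SeqRecord
from .read_mapping import MappingParams
from .synthetic_data import (
    DivergenceConfig,
    ReadSimConfig,
    TruthRegistry,
    derive_accession,
    generate_ancestor,
    simulate_reads,
)
from .zcr_pav import ReciprocalResult, ZcrParams, run_reciprocal, summarize_bins

__all__ = ["RunConfig", "BenchmarkReport", "stage_seeds", "run_benchmark", "run_report"]


def stage_seeds(global_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage seeds (all below 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s % (2 ** 31)) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class RunConfig:
    """Resolved configuration of one benchmark run."""

    genome_length: int = 1_000_000
    gc: float = 0.36
    repeat_specs: tuple = ()
    divergence: DivergenceConfig = field(default_factory=lambda: DivergenceConfig(
        n_insertions=20, n_deletions=20, large_event_len_range=(100, 10_000)))
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)
    mapping: MappingParams = field(default_factory=MappingParams)
    zcr: ZcrParams = field(default_factory=ZcrParams)
    seed: int = 0

    def resolved(self) -> "RunConfig":
        """Fan the global seed out into the per-stage configs."""
        s = stage_seeds(self.seed, 4)
        cfg = RunConfig(**{**asdict_shallow(self)})
        cfg.divergence.seed = s[0]
        cfg.read_sim.seed = s[1]
        cfg.mapping.seed = s[2]
        return cfg


def asdict_shallow(cfg: RunConfig) -> dict:
    import copy
    return {k: copy.deepcopy(getattr(cfg, k)) for k in (
        "genome_length", "gc", "repeat_specs", "divergence", "read_sim",
        "mapping", "zcr", "seed")}


@dataclass
class BenchmarkReport:
    """Recovery scores of one seeded benchmark run."""

    config: dict
    n_truth_insertions: int
    n_truth_deletions: int
    recall_insertions: float
    recall_deletions: float
    recall: float
    n_pav_calls: int
    n_false_pav: int
    direction_accuracy: float
    boundary_within_tol: float
    bins_insertions: dict
    bins_deletions: dict
    n_hdr_calls: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict_report(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def asdict_report(rep: BenchmarkReport) -> dict:
    from dataclasses import asdict as dc_asdict
    return dc_asdict(rep)


def _overlap(s1, e1, s2, e2):
    return min(e1, e2) - max(s1, s2)


def score_against_truth(result: ReciprocalResult, registry: TruthRegistry,
                        zcr_params: ZcrParams, margin: int = 1000):
    """Join reciprocal PAV calls to the truth ledger.

    Truth insertions (novel in the derived accession B) should surface as
    PAV in the A-reads-on-B direction at their B interval; truth deletions
    (lost from B) as PAV in the B-reads-on-A direction at their A interval.
    A call is false when no truth large event lies within ``margin`` bp.
    """
    ins_truth = [(v.b_start, v.b_end) for v in registry.by_type("insertion")]
    del_truth = [(v.a_start, v.a_end) for v in registry.by_type("deletion")]
    # opposite-class events expressed in the frame the calls live in:
    # a deletion in B is a point on B, an insertion in B is a point on A
    del_in_b = [(v.b_start, v.b_end) for v in registry.by_type("deletion")]
    ins_in_a = [(v.a_start, v.a_end) for v in registry.by_type("insertion")]
    dup_truth = [(v.b_start, v.b_end) for v in registry.by_type("cnv_collapse")]
    directions = {
        "insertion": (result.a_reads_on_b, ins_truth),
        "deletion": (result.b_reads_on_a, del_truth),
    }
    matched = {"insertion": set(), "deletion": set()}
    wrong_direction = {"insertion": set(), "deletion": set()}
    n_false = 0
    n_boundary_ok = 0
    n_matched_calls = 0
    matched_lengths = {"insertion": [], "deletion": []}
    for kind, (direction, truth) in directions.items():
        other_truth = del_in_b if kind == "insertion" else ins_in_a
        for call in direction.pav_calls:
            s, e = call.zcr.interval.start, call.zcr.interval.end
            hit = None
            for i, (ts, te) in enumerate(truth):
                if _overlap(s, e, ts - margin, te + margin) > 0:
                    hit = i
                    break
            if hit is not None:
                matched[kind].add(hit)
                n_matched_calls += 1
                ts, te = truth[hit]
                tol = zcr_params.adjacency_tolerance(te - ts)
                if abs((e - s) - (te - ts)) <= tol:
                    n_boundary_ok += 1
                matched_lengths[kind].append(e - s)
                continue
            # events of the opposite class live on the other assembly, so a
            # call overlapping one here carries a wrong direction label
            near_other = any(
                _overlap(s, e, ts - margin, te + margin) > 0 for ts, te in other_truth
            )
            near_dup = kind == "insertion" and any(
                _overlap(s, e, ts - margin, te + margin) > 0 for ts, te in dup_truth
            )
            if near_other:
                wrong_direction[kind].add((s, e))
            elif not near_dup:
                n_false += 1
    n_ins, n_del = len(ins_truth), len(del_truth)
    recall_i = len(matched["insertion"]) / n_ins if n_ins else float("nan")
    recall_d = len(matched["deletion"]) / n_del if n_del else float("nan")
    n_truth = n_ins + n_del
    recall = (len(matched["insertion"]) + len(matched["deletion"])) / n_truth if n_truth else float("nan")
    n_wrong = len(wrong_direction["insertion"]) + len(wrong_direction["deletion"])
    denom = n_matched_calls + n_wrong
    direction_acc = n_matched_calls / denom if denom else float("nan")
    boundary_frac = n_boundary_ok / n_matched_calls if n_matched_calls else float("nan")
    return {
        "recall_insertions": recall_i,
        "recall_deletions": recall_d,
        "recall": recall,
        "n_false_pav": n_false,
        "direction_accuracy": direction_acc,
        "boundary_within_tol": boundary_frac,
        "n_matched_calls": n_matched_calls,
        "matched_lengths": matched_lengths,
    }


def run_benchmark(config: RunConfig | None = None) -> BenchmarkReport:
    """Generate a synthetic pair, run the reciprocal analysis, score it."""
    config = (config or RunConfig()).resolved()
    ancestor = generate_ancestor(
        config.genome_length, gc=config.gc, repeat_specs=config.repeat_specs,
        seed=stage_seeds(config.seed, 5)[4],
    )
    derived, registry = derive_accession(ancestor, config.divergence)
    accession_a = SeqRecord("accA", ancestor.record.sequence)
    accession_b = SeqRecord("accB", derived.sequence)

    sim_a = simulate_reads(accession_a, config.read_sim)
    cfg_b = ReadSimConfig(**{**vars(config.read_sim)})
    cfg_b.seed = (config.read_sim.seed + 1) % (2 ** 31)
    sim_b = simulate_reads(accession_b, cfg_b)

    result = run_reciprocal(
        sim_a.records, sim_b.records, accession_a, accession_b,
        config.mapping, config.zcr, name_a="accA", name_b="accB",
    )
    scores = score_against_truth(result, registry, config.zcr)
    n_hdr = len(result.a_reads_on_b.hdr_calls) + len(result.b_reads_on_a.hdr_calls)
    bins_i = summarize_bins(result.a_reads_on_b.pav_calls)
    bins_d = summarize_bins(result.b_reads_on_a.pav_calls)
    return BenchmarkReport(
        config=_config_dict(config),
        n_truth_insertions=len(registry.by_type("insertion")),
        n_truth_deletions=len(registry.by_type("deletion")),
        recall_insertions=scores["recall_insertions"],
        recall_deletions=scores["recall_deletions"],
        recall=scores["recall"],
        n_pav_calls=len(result.a_reads_on_b.pav_calls) + len(result.b_reads_on_a.pav_calls),
        n_false_pav=scores["n_false_pav"],
        direction_accuracy=scores["direction_accuracy"],
        boundary_within_tol=scores["boundary_within_tol"],
        bins_insertions={"counts": bins_i.counts, "bps": bins_i.bps},
        bins_deletions={"counts": bins_d.counts, "bps": bins_d.bps},
        n_hdr_calls=n_hdr,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["repeat_specs"] = [list(t) for t in d["repeat_specs"]]
    return d


# ---------------------------------------------------------------------------

REPORT_SECTIONS = ("assembly_stats", "size_bins", "rbh", "composition")


def run_report(assembly_stats=None, size_bins=None, rbh_summary=None,
               composition=None, path=None):
    """Consolidate stage outputs into one JSON-able report.

    Only the sections whose inputs are present appear; totals are recomputed
    from the per-bin rows so they always match the stage outputs.
    """
    report: dict = {"sections": []}
    if assembly_stats is not None:
        report["assembly_stats"] = asdict(assembly_stats)
        report["sections"].append("assembly_stats")
    if size_bins is not None:
        section = {}
        for name, summary in size_bins.items():
            section[name] = {
                "counts": summary.counts,
                "bps": summary.bps,
                "total_count": summary.total_count,
                "total_bp": summary.total_bp,
            }
        report["size_bins"] = section
        report["sections"].append("size_bins")
    if rbh_summary is not None:
        report["rbh"] = dict(rbh_summary)
        report["sections"].append("rbh")
    if composition is not None:
        report["composition"] = {
            "genome_size_est": composition.genome_size_est,
            "assembly_len": composition.assembly_len,
            "nor_size": composition.nor_size,
            "unassembled": composition.unassembled,
            "centromeric_total": composition.centromeric_total,
            "per_centromere": composition.per_centromere,
        }
        report["sections"].append("composition")
    validate_report(report)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def validate_report(report: dict):
    """Structural validation of a consolidated report."""
    if "sections" not in report or not isinstance(report["sections"], list):
        raise ValueError("report missing 'sections' list")
    for sec in report["sections"]:
        if sec not in REPORT_SECTIONS:
            raise ValueError(f"unknown report section {sec!r}")
        if sec not in report:
            raise ValueError(f"section {sec!r} listed but absent")
    if "size_bins" in report:
        for name, s in report["size_bins"].items():
            if s["total_count"] != sum(s["counts"]) or s["total_bp"] != sum(s["bps"]):
                raise ValueError(f"size-bin totals inconsistent in {name!r}")
    return True
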
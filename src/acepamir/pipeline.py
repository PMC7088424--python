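"""Pipeline orchestration: scan -> fold -> evaluate -> targets -> phylo.

One flat key=value config drives all stages; reports are TSV tables
mirroring the per-precursor statistics layout of published EST/GSS
miRNA surveys (per-hit table, per-precursor statistics, sequence +
composition table, parameter summary, target table), plus a Newick
tree and a dot-bracket structure file.  Logging records the number of
candidates surviving each filter stage.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from .fold import DEFAULT_FLANK_STEPS, extract_precursor_windows
from .hairpin import HairpinEvaluation, HairpinThresholds, evaluate_hairpin
from .homology import ReferenceMature, dereplicate, orf_coding_filter, scan_candidates
from .phylo import bootstrap_support
from .targets import scan_transcript

log = logging.getLogger("acepamir")

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with conventional defaults."""

    subjects: str = ""
    references: str = ""
    transcripts: str = ""            # optional
    go_mapping: str = ""             # optional TSV: target_id, go_id, category, description
    out_dir: str = "acepamir_out"
    max_mismatch: int = 3
    min_match: int = 18
    min_orf_codons: int = 80
    flank_steps: tuple[int, ...] = DEFAULT_FLANK_STEPS
    min_lp: int = 60
    max_lp: int = 400
    min_paired_fraction: float = 0.5
    max_duplex_bulge: int = 4
    max_asymmetric_bulges: int = 1
    min_pct_au: float = 30.0
    max_pct_au: float = 70.0
    mfei_min: float = 0.85
    expectation_cutoff: float = 3.0
    max_targets: int = 10
    bootstrap_replicates: int = 1000
    seed: int = 1

    def thresholds(self) -> HairpinThresholds:
        return HairpinThresholds(
            min_paired_fraction=self.min_paired_fraction,
            max_duplex_bulge=self.max_duplex_bulge,
            max_asymmetric_bulges=self.max_asymmetric_bulges,
            min_pct_au=self.min_pct_au,
            max_pct_au=self.max_pct_au,
            mfei_min=self.mfei_min,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line {lineno}: {line!r}")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r} (line {lineno})")
                f = types[key]
                if f.type in ("int",):
                    kwargs[key] = int(raw)
                elif f.type in ("float",):
                    kwargs[key] = float(raw)
                elif "tuple" in str(f.type):
                    kwargs[key] = tuple(int(x) for x in raw.split(",") if x != "")
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    hits: list = field(default_factory=list)
    evaluations: list = field(default_factory=list)       # passing, best per subject
    all_evaluations: list = field(default_factory=list)   # best candidate per hit
    target_alignments: list = field(default_factory=list)
    tree_newick: str = ""
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Stage order: homology scan, dereplication, coding-sequence removal,
    precursor window folding, hairpin evaluation, then (optionally)
    target scanning and NJ phylogenetics of the passing precursors.
    A failing stage aborts with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    counts = result.stage_counts

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    subjects = stage("read_subjects", seqio.read_fasta, config.subjects)
    refs_records = stage("read_references", seqio.read_fasta, config.references, "reference")
    references = [ReferenceMature(id=r.id, sequence=r.sequence) for r in refs_records]
    counts["subjects"] = len(subjects)
    counts["references"] = len(references)

    hits = stage("scan", scan_candidates, references, subjects,
                 config.max_mismatch, config.min_match)
    counts["hits"] = len(hits)
    hits = stage("dereplicate", dereplicate, hits)
    counts["hits_dereplicated"] = len(hits)

    by_id = {s.id: s for s in subjects}
    coding_ids = {s.id for s in subjects
                  if orf_coding_filter(s, config.min_orf_codons)}
    hits = [h for h in hits if h.subject_id not in coding_ids]
    counts["hits_noncoding"] = len(hits)
    result.hits = hits
    log.info("scan: %d hits on %d subjects; %d survive dereplication; "
             "%d after coding-sequence removal",
             counts["hits"], counts["subjects"],
             counts["hits_dereplicated"], counts["hits_noncoding"])

    seqio.write_tsv(
        [
            {
                "subject_id": h.subject_id, "reference_id": h.reference_id,
                "start": h.start, "end": h.end, "strand": h.strand,
                "length": h.matched_length, "mismatches": h.mismatches,
            }
            for h in hits
        ],
        out / "hits.tsv",
        columns=["subject_id", "reference_id", "start", "end", "strand",
                 "length", "mismatches"],
    )

    thresholds = config.thresholds()
    best_per_hit: list[HairpinEvaluation] = []
    for hit in hits:
        cands = stage(
            "fold", extract_precursor_windows, by_id[hit.subject_id], hit,
            tuple(config.flank_steps), config.min_lp, config.max_lp,
        )
        evals = [evaluate_hairpin(c, thresholds) for c in cands]
        passing = [e for e in evals if e.passes]
        chosen = passing[0] if passing else (evals[0] if evals else None)
        if chosen is not None:
            chosen.hit = hit
            best_per_hit.append(chosen)
    result.all_evaluations = best_per_hit
    counts["folded_hits"] = len(best_per_hit)

    # best passing candidate per subject locus; a mature and its star arm
    # match the same hairpin, so overlapping windows collapse to one locus
    passing = _collapse_loci([e for e in best_per_hit if e.passes])
    counts["passing_hairpins"] = len(passing)
    result.evaluations = passing
    log.info("hairpin evaluation: %d/%d loci pass all criteria",
             len(passing), len(best_per_hit))

    _write_precursor_tables(out, passing)
    seqio.write_dotbracket(
        [
            (e.hit.subject_id + f"|{e.candidate.window_interval[0]}-{e.candidate.window_interval[1]}",
             e.candidate.precursor_sequence, e.candidate.fold.structure, e.mfe)
            for e in passing
        ],
        out / "structures.dbn",
    )
    if passing:
        seqio.write_tsv(summarize_stats(passing), out / "summary.tsv")

    if config.transcripts:
        transcripts = stage("read_transcripts", seqio.read_fasta,
                            config.transcripts, "transcript")
        alignments = []
        for e in passing:
            mat = ReferenceMature(
                id=f"{e.hit.reference_id}@{e.hit.subject_id}",
                sequence=e.mature_sequence,
            )
            for t in transcripts:
                alignments.extend(
                    stage("targets", scan_transcript, mat, t,
                          config.expectation_cutoff, config.max_targets)
                )
        result.target_alignments = alignments
        counts["target_alignments"] = len(alignments)
        seqio.write_tsv(
            [
                {
                    "mirna": a.mirna_id, "target_id": a.transcript_id,
                    "site_start": a.site_interval[0], "site_end": a.site_interval[1],
                    "fragment": a.site_sequence, "expectation": a.expectation,
                    "upe": "" if a.upe is None else a.upe,
                    "inhibition": a.inhibition,
                }
                for a in alignments
            ],
            out / "targets.tsv",
            columns=["mirna", "target_id", "site_start", "site_end",
                     "fragment", "expectation", "upe", "inhibition"],
        )

    if len(passing) >= 3:
        seqs = {
            "{}@{}_{}-{}".format(
                e.hit.reference_id, e.hit.subject_id,
                e.candidate.window_interval[0], e.candidate.window_interval[1],
            ): e.candidate.precursor_sequence
            for e in passing
        }
        if len(seqs) >= 3:
            tree = stage("phylo", bootstrap_support, seqs,
                         config.bootstrap_replicates, config.seed)
            result.tree_newick = seqio.write_newick(tree, out / "tree.nwk")

    if config.go_mapping:
        rows = seqio.read_tsv(config.go_mapping)
        mapping = [
            (r["target_id"], r["go_id"], r["category"], r.get("description", ""))
            for r in rows
        ]
        seqio.write_tsv(go_tabulate(mapping), out / "go_summary.tsv",
                        columns=["category", "go_id", "description", "n_genes"])

    log.info("pipeline finished: %s", counts)
    return result


def _collapse_loci(evaluations: list[HairpinEvaluation]) -> list[HairpinEvaluation]:
    """One evaluation per precursor locus.

    Evaluations on the same subject whose precursor windows overlap by
    at least half of the shorter window describe the same hairpin
    (typically the mature-arm and star-arm hits); the one with fewer
    hit mismatches wins (ties: larger |MFEI|, then leftmost window).
    """
    ranked = sorted(
        evaluations,
        key=lambda e: (e.hit.subject_id, e.hit.mismatches, -abs(e.mfei),
                       e.candidate.window_interval),
    )
    kept: list[HairpinEvaluation] = []
    for ev in ranked:
        s, t = ev.candidate.window_interval
        clash = False
        for other in kept:
            if other.hit.subject_id != ev.hit.subject_id:
                continue
            os_, ot = other.candidate.window_interval
            ov = min(t, ot) - max(s, os_) + 1
            if ov > 0 and 2 * ov >= min(t - s + 1, ot - os_ + 1):
                clash = True
                break
        if not clash:
            kept.append(ev)
    kept.sort(key=lambda e: (e.hit.subject_id, e.candidate.window_interval))
    return kept


def _write_precursor_tables(out: Path, evaluations: list[HairpinEvaluation]) -> None:
    stats_rows = []
    seq_rows = []
    for e in evaluations:
        h = e.hit
        c = e.candidate
        comp = e.comp.rounded()
        stats_rows.append(
            {
                "reference_id": h.reference_id, "subject_id": h.subject_id,
                "precursor_length": e.lp,
                "mature_length": len(e.mature_sequence),
                "arm": e.arm, "strand": h.strand, "mismatches": h.mismatches,
                "pct_gc": round(comp.pct_gc, 2), "mfe": round(e.mfe, 2),
                "amfe": round(e.amfe, 2), "mfei": round(e.mfei, 2),
            }
        )
        seq_rows.append(
            {
                "reference_id": h.reference_id, "subject_id": h.subject_id,
                "mature": e.mature_sequence, "precursor": c.precursor_sequence,
                "pct_a": comp.pct_a, "pct_u": comp.pct_u,
                "pct_g": comp.pct_g, "pct_c": comp.pct_c,
                "five_prime_nt": e.five_prime_nt,
            }
        )
    seqio.write_tsv(stats_rows, out / "precursors.tsv",
                    columns=["reference_id", "subject_id", "precursor_length",
                             "mature_length", "arm", "strand", "mismatches",
                             "pct_gc", "mfe", "amfe", "mfei"])
    seqio.write_tsv(seq_rows, out / "sequences.tsv",
                    columns=["reference_id", "subject_id", "mature", "precursor",
                             "pct_a", "pct_u", "pct_g", "pct_c", "five_prime_nt"])


def summarize_stats(evaluations: list[HairpinEvaluation]) -> list[dict]:
    """Min/max/mean/sample-SD summary rows for each precursor parameter."""
    if not evaluations:
        raise ValueError("no evaluations to summarize")
    params = {
        "precursor_length": [float(e.lp) for e in evaluations],
        "pct_au": [e.comp.pct_au for e in evaluations],
        "pct_gc": [e.comp.pct_gc for e in evaluations],
        "pct_a": [e.comp.pct_a for e in evaluations],
        "pct_u": [e.comp.pct_u for e in evaluations],
        "pct_g": [e.comp.pct_g for e in evaluations],
        "pct_c": [e.comp.pct_c for e in evaluations],
        "mfe": [e.mfe for e in evaluations],
        "amfe": [e.amfe for e in evaluations],
        "mfei": [e.mfei for e in evaluations],
    }
    rows = []
    for name, values in params.items():
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(
            {
                "parameter": name,
                "minimum": round(float(arr.min()), 2),
                "maximum": round(float(arr.max()), 2),
                "mean": round(float(arr.mean()), 2),
                "sd": round(sd, 2),
            }
        )
    return rows


def go_tabulate(mapping: list[tuple]) -> list[dict]:
    """Count distinct target genes per GO term, grouped by category.

    *mapping* rows are (target_id, go_id, category, description);
    duplicated (gene, term) pairs count once.  Malformed GO ids raise
    with the offending row named.
    """
    if not mapping:
        raise ValueError("empty GO mapping")
    categories = ("biological process", "molecular function", "cellular component")
    genes: dict[tuple[str, str], set] = {}
    descs: dict[tuple[str, str], str] = {}
    for idx, (target_id, go_id, category, description) in enumerate(mapping, start=1):
        if not _GO_RE.match(go_id):
            raise ValueError(f"malformed GO id {go_id!r} in mapping row {idx}")
        cat = category.lower()
        if cat not in categories:
            raise ValueError(f"unknown GO category {category!r} in mapping row {idx}")
        key = (cat, go_id)
        genes.setdefault(key, set()).add(target_id)
        descs.setdefault(key, description)
    rows = []
    for cat in categories:
        for (c, go_id) in sorted(k for k in genes if k[0] == cat):
            rows.append(
                {
                    "category": cat,
                    "go_id": go_id,
                    "description": descs[(cat, go_id)],
                    "n_genes": len(genes[(cat, go_id)]),
                }
            )
    return rows
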
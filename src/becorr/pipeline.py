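"""Stage functions tying the analysis modules to files on disk.

Each stage reads and writes plain TSV/FASTA/FASTQ and is what the CLI
subcommands call; :func:`run_pipeline` chains them with resume support
and a run manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from becorr import annotate as ann
from becorr import classify as cls
from becorr import guides as gd
from becorr import outcomes as oc
from becorr import quant as qt
from becorr import scoring as sc
from becorr.io import file_checksum, read_sample_sheet, read_tsv, write_manifest, write_tsv

logger = logging.getLogger(__name__)


def stage_design(fasta, editor: str, pam: str, out, controls=None) -> pd.DataFrame:
    refs = gd.read_references(fasta)
    guides = gd.enumerate_guides(refs, editor.upper(), pam.upper())
    guides = gd.filter_unique(guides, refs)
    df = gd.guides_to_frame(guides)
    if controls is not None:
        df = gd.apply_control_annotations(df, read_tsv(controls))
    write_tsv(df, out, "design", {"editor": editor, "pam": pam})
    return df


def extract_assay_records(
    fastq_path,
    sample_id: str,
    scaffold: str,
    max_mismatch: int = 3,
    target_len: int = 26,
    target_upstream: int = 3,
) -> list[oc.PairedReadRecord]:
    records = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        r = oc.anchor_and_extract(
            str(rec.seq).upper(), scaffold, max_mismatch=max_mismatch,
            target_len=target_len, read_id=f"{sample_id}:{rec.id}",
        )
        if r is not None:
            records.append(r)
    return oc.flag_recombinants(records, target_upstream=target_upstream)


def map_outcomes(
    reads_by_sample: Mapping[str, Sequence[oc.PairedReadRecord]],
    sample_sheet: pd.DataFrame,
    library: Sequence[gd.GuideDesign],
    transcripts: Mapping[str, ann.TranscriptModel],
    refs: Mapping[str, str],
    target_upstream: int = 3,
    target_len: int = 26,
    min_coverage: int = oc.MIN_COVERAGE,
    min_frequency: float = oc.MIN_FREQUENCY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory outcome mapping across edited and control samples."""
    cond = dict(zip(sample_sheet["sample_id"], sample_sheet["condition"]))
    edited_samples = [s for s, c in cond.items() if c == "edited"]
    control_samples = [s for s, c in cond.items() if c == "control"]
    if not edited_samples:
        raise ValueError("no edited samples in sample sheet")

    def tallies(samples):
        recs, owner = [], {}
        for s in samples:
            for r in reads_by_sample.get(s, []):
                recs.append(r)
                owner[r.read_id] = s
        recs = oc.assign_to_library(recs, library, target_upstream=target_upstream)
        return oc.tally_outcomes(
            recs, library, refs, sample_of_record=owner, sample_ids=samples,
            target_upstream=target_upstream, target_len=target_len,
        )

    edited_t = tallies(edited_samples)
    control_t = tallies(control_samples) if control_samples else pd.DataFrame(
        columns=["guide_id", "sample_id", "outcome_key", "R", "D"])
    h_c = oc.background_rates(control_t)
    fractions = oc.corrected_fractions(edited_t, h_c)
    if fractions.empty:
        raise ValueError("no outcomes survived extraction/assignment")

    by_id = {g.guide_id: g for g in library}
    by_contig = {}
    for t in transcripts.values():
        by_contig.setdefault(t.contig, []).append(t)
    ann_rows = []
    for row in fractions[["guide_id", "outcome_key"]].drop_duplicates().itertuples(index=False):
        g = by_id[row.guide_id]
        changes = ann.guide_changes_from_key(g, row.outcome_key)
        model = _pick_transcript(by_contig.get(g.contig, []), changes)
        if model is None:
            aa, mtype = [], "unannotated"
        else:
            aa, mtype = ann.annotate_outcome(changes, model, refs)
        ann_rows.append({
            "guide_id": row.guide_id,
            "outcome_key": row.outcome_key,
            "nucleotide_changes": ann.format_nt_changes(changes),
            "aa_changes": ann.format_aa_changes(aa),
            "mutational_type": mtype,
        })
    annotations = pd.DataFrame(ann_rows)
    return oc.merge_and_pick_major(
        fractions, annotations, edited_samples,
        min_coverage=min_coverage, min_frequency=min_frequency,
    )


def _pick_transcript(models, changes):
    if not models:
        return None
    for m in models:
        lo, hi = m.span
        if any(lo <= pos < hi for pos, _r, _a in changes):
            return m
    return models[0]


def stage_map_outcomes(
    reads: Mapping[str, str],
    samples,
    library_tsv,
    transcripts_tsv,
    fasta,
    out_prefix,
    scaffold: str,
    max_mismatch: int = 3,
    target_len: int = 26,
    target_upstream: int = 3,
    min_coverage: int = oc.MIN_COVERAGE,
    min_frequency: float = oc.MIN_FREQUENCY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sheet = read_sample_sheet(samples)
    lib_df = read_tsv(library_tsv)
    library = gd.frame_to_guides(lib_df[lib_df["control_class"] == "targeting"])
    transcripts = ann.transcripts_from_frame(read_tsv(transcripts_tsv))
    refs = gd.read_references(fasta)
    reads_by_sample = {
        s: extract_assay_records(path, s, scaffold, max_mismatch, target_len,
                                 target_upstream)
        for s, path in reads.items()
    }
    outcomes, efficiency = map_outcomes(
        reads_by_sample, sheet, library, transcripts, refs,
        target_upstream=target_upstream, target_len=target_len,
        min_coverage=min_coverage, min_frequency=min_frequency,
    )
    params = {"scaffold_len": len(scaffold), "target_len": target_len,
              "min_coverage": min_coverage, "min_frequency": min_frequency}
    write_tsv(outcomes, f"{out_prefix}.outcomes.tsv", "map-outcomes", params)
    write_tsv(efficiency, f"{out_prefix}.efficiency.tsv", "map-outcomes", params)
    return outcomes, efficiency


def stage_quantify(
    out,
    samples,
    library_tsv,
    counts_tsv=None,
    reads: Mapping[str, str] | None = None,
    pseudocount: float = 1.0,
    count_mode: str = "scan",
) -> pd.DataFrame:
    sheet = read_sample_sheet(samples)
    library = read_tsv(library_tsv)
    if counts_tsv is not None:
        counts = read_tsv(counts_tsv).set_index("guide_id")
    elif reads is not None:
        counts = qt.count_guides(reads, library, mode=count_mode)
    else:
        raise ValueError("provide either a counts TSV or FASTQ reads")
    fc, w = qt.quantify(counts, sheet, library, pseudocount=pseudocount)
    write_tsv(fc, out, "quantify", {"pseudocount": pseudocount,
                                    "w": ";".join(f"{s}={v:.4g}" for s, v in w.items())})
    return fc


def stage_score(
    foldchanges_tsv,
    efficiency_tsv,
    out,
    predicted_tsv=None,
    activity_floor: float = sc.DEFAULT_ACTIVITY_FLOOR,
    activity_filter: float | None = None,
) -> pd.DataFrame:
    fc = read_tsv(foldchanges_tsv)
    eff = read_tsv(efficiency_tsv)
    pred = read_tsv(predicted_tsv) if predicted_tsv else None
    scores = sc.score_table(fc, eff, pred, activity_floor=activity_floor,
                            activity_filter=activity_filter)
    write_tsv(scores, out, "score", {"activity_floor": activity_floor,
                                     "activity_filter": activity_filter})
    return scores


def stage_classify(
    scores_tsv,
    out_prefix,
    labels_tsv=None,
    threshold: float = cls.LOF_POSTERIOR_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    import json

    scores = read_tsv(scores_tsv)
    calls, report = cls.classify_scores(scores, threshold=threshold, seed=seed)
    filt = scores["filtered"].astype(bool) if "filtered" in scores.columns else \
        pd.Series(False, index=scores.index)
    report["model_selection"] = cls.model_selection_report(
        scores.loc[~filt, "mean_beta"].dropna(), seed=seed,
    ).to_dict(orient="records")
    labels = None
    if labels_tsv:
        lab_df = read_tsv(labels_tsv)
        labels = lab_df.set_index(lab_df.columns[0])[lab_df.columns[1]]
    evaluation = cls.evaluate(calls.set_index("guide_id"), labels)
    write_tsv(calls, f"{out_prefix}.calls.tsv", "classify",
              {"threshold": threshold, "seed": seed})
    if "enrichment" in evaluation:
        write_tsv(evaluation["enrichment"], f"{out_prefix}.enrichment.tsv",
                  "classify", {})
    scalar_eval = {k: v for k, v in evaluation.items() if not isinstance(v, pd.DataFrame)}
    with open(f"{out_prefix}.fit.json", "w") as fh:
        json.dump({"fit": report, "evaluation": scalar_eval}, fh, indent=2, default=float)
        fh.write("\n")
    return calls, report


def run_pipeline(config: dict, force: bool = False) -> list[dict]:
    """Run design -> map-outcomes -> quantify -> score -> classify.

    ``config`` holds per-stage sub-dicts (see the CLI help); stages whose
    outputs already exist are skipped unless ``force``.  Returns the
    manifest stage list (also written to <outdir>/manifest.json).
    """
    outdir = Path(config.get("outdir", "becorr_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name, outputs, params, ran):
        stages.append({
            "stage": name, "ran": ran, "params": params,
            "outputs": {str(p): file_checksum(p) for p in outputs if Path(p).exists()},
        })

    design_cfg = config["design"]
    library_tsv = outdir / "library.tsv"
    if force or not library_tsv.exists():
        stage_design(design_cfg["fasta"], design_cfg.get("editor", "cbe"),
                     design_cfg.get("pam", "ngg"), library_tsv,
                     controls=design_cfg.get("controls"))
        ran = True
    else:
        ran = False
    record("design", [library_tsv], design_cfg, ran)

    mo = config["map_outcomes"]
    out_prefix = outdir / "assay"
    eff_tsv = Path(f"{out_prefix}.efficiency.tsv")
    if force or not eff_tsv.exists():
        stage_map_outcomes(
            mo["reads"], mo["samples"], library_tsv, mo["transcripts"],
            design_cfg["fasta"], out_prefix, mo["scaffold"],
            target_len=mo.get("target_len", 26),
            min_coverage=mo.get("min_coverage", oc.MIN_COVERAGE),
            min_frequency=mo.get("min_frequency", oc.MIN_FREQUENCY),
        )
        ran = True
    else:
        ran = False
    record("map-outcomes", [eff_tsv], {k: str(v) for k, v in mo.items()}, ran)

    qc = config["quantify"]
    fc_tsv = outdir / "foldchanges.tsv"
    if force or not fc_tsv.exists():
        stage_quantify(fc_tsv, qc["samples"], library_tsv,
                       counts_tsv=qc.get("counts"), reads=qc.get("reads"),
                       pseudocount=qc.get("pseudocount", 1.0))
        ran = True
    else:
        ran = False
    record("quantify", [fc_tsv], {k: str(v) for k, v in qc.items()}, ran)

    sco = config.get("score", {})
    scores_tsv = outdir / "scores.tsv"
    if force or not scores_tsv.exists():
        stage_score(fc_tsv, eff_tsv, scores_tsv,
                    predicted_tsv=sco.get("predicted"),
                    activity_floor=sco.get("activity_floor", sc.DEFAULT_ACTIVITY_FLOOR),
                    activity_filter=sco.get("activity_filter"))
        ran = True
    else:
        ran = False
    record("score", [scores_tsv], sco, ran)

    cc = config.get("classify", {})
    calls_prefix = outdir / "lof"
    calls_tsv = Path(f"{calls_prefix}.calls.tsv")
    if force or not calls_tsv.exists():
        stage_classify(scores_tsv, calls_prefix, labels_tsv=cc.get("labels"),
                       threshold=cc.get("threshold", cls.LOF_POSTERIOR_THRESHOLD),
                       seed=cc.get("seed", 0))
        ran = True
    else:
        ran = False
    record("classify", [calls_tsv, Path(f"{calls_prefix}.fit.json")], cc, ran)

    write_manifest(outdir / "manifest.json", stages)
    return stages
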
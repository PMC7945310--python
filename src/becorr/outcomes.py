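"""Editing-outcome and efficiency mapping from paired guide-target reads.

The integrated target-site assay couples each sgRNA spacer with a copy of
its own target sequence on one amplicon: ``spacer - scaffold - target``.
Reads are anchored on the scaffold, recombinant molecules (spacer and
target from different library members, a lentiviral template-switching
artifact) are removed by Jaro similarity, reads are assigned to the
designed library, canonical base-editing outcomes are called within the
protospacer window, corrected for background error measured in unedited
control samples, annotated, and merged at the amino-acid level.

The corrected fraction of outcome k is

    f_k = mean_j [ (R_kj - D_j * h_c) / (D_j - D_j * h_c) ]

over edited samples j with assigned depth D_j > 0, where R_kj is the
number of reads carrying outcome k and h_c the mean fraction of reads
carrying k's changes in the control samples.  Negative corrected values
are clamped to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from becorr.guides import (
    EDITOR_ALT_BASE,
    EDITOR_TARGET_BASE,
    EDIT_WINDOW,
    PAM_LENGTHS,
    PAM_PATTERNS,
    SPACER_LEN,
    GuideDesign,
)

logger = logging.getLogger(__name__)

JARO_THRESHOLD = 0.75
ASSIGN_IDENTITY = 0.85  # <=3 mismatches over a 20-nt spacer
MIN_COVERAGE = 30
MIN_FREQUENCY = 0.005


@dataclass
class PairedReadRecord:
    """Spacer and target segments extracted around the scaffold anchor."""

    read_id: str
    spacer_obs: str
    target_obs: str
    scaffold_mismatches: int = 0
    guide_id: str | None = None
    recombinant: bool = False


def jaro_similarity(a: str, b: str) -> float:
    """Jaro similarity in [0, 1].

    Matches are equal characters within ``floor(max(|a|,|b|)/2) - 1``
    positions of each other; the transposition term halves the count of
    matched characters that are out of order.  An empty string scores 0
    against a non-empty string and 1 against another empty string.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    window = max(len(a), len(b)) // 2 - 1
    a_match = [False] * len(a)
    b_match = [False] * len(b)
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(len(b), i + window + 1)
        for j in range(lo, hi):
            if not b_match[j] and b[j] == ca:
                a_match[i] = True
                b_match[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i, matched in enumerate(a_match):
        if not matched:
            continue
        while not b_match[j]:
            j += 1
        if a[i] != b[j]:
            transpositions += 1
        j += 1
    t = transpositions / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def anchor_and_extract(
    read_seq: str,
    scaffold: str,
    max_mismatch: int = 3,
    spacer_len: int = SPACER_LEN,
    target_len: int = 26,
    read_id: str = "",
) -> PairedReadRecord | None:
    """Locate the scaffold in ``read_seq`` and cut out spacer and target.

    The scaffold is placed by minimal Hamming distance over all full-length
    windows.  Rejection (returns None) when the best distance exceeds
    ``max_mismatch``, the best placement is ambiguous (tied), or the flanks
    are shorter than ``spacer_len`` / ``target_len``.
    """
    L, S = len(read_seq), len(scaffold)
    if S < 20:
        raise ValueError("scaffold must be at least 20 nt")
    if L < S:
        return None
    # exact hit is the common case; fall back to vectorized Hamming scan
    exact = read_seq.find(scaffold)
    if exact != -1 and read_seq.find(scaffold, exact + 1) == -1:
        best_d, best_pos = 0, exact
    else:
        arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, S)
        dists = (windows != np.frombuffer(scaffold.encode(), dtype=np.uint8)).sum(axis=1)
        best_d = int(dists.min())
        hits = np.flatnonzero(dists == best_d)
        if best_d > max_mismatch or hits.size != 1:
            return None
        best_pos = int(hits[0])
    if best_d > max_mismatch:
        return None
    if best_pos < spacer_len or L - (best_pos + S) < target_len:
        return None
    return PairedReadRecord(
        read_id=read_id,
        spacer_obs=read_seq[best_pos - spacer_len : best_pos],
        target_obs=read_seq[best_pos + S : best_pos + S + target_len],
        scaffold_mismatches=best_d,
    )


def flag_recombinants(
    records: Iterable[PairedReadRecord],
    target_upstream: int = 3,
    threshold: float = JARO_THRESHOLD,
) -> list[PairedReadRecord]:
    """Flag reads whose spacer and in-target protospacer disagree.

    The protospacer copy inside the target segment starts ``target_upstream``
    nt in; Jaro similarity below ``threshold`` marks the read recombinant.
    """
    out = []
    for rec in records:
        proto_in_target = rec.target_obs[target_upstream : target_upstream + SPACER_LEN]
        rec.recombinant = jaro_similarity(rec.spacer_obs, proto_in_target) < threshold
        out.append(rec)
    return out


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def assign_to_library(
    records: Iterable[PairedReadRecord],
    library: Sequence[GuideDesign],
    target_upstream: int = 3,
    identity: float = ASSIGN_IDENTITY,
) -> list[PairedReadRecord]:
    """Assign each record's observed spacer to a designed guide.

    Exact spacer matches are taken directly.  Otherwise the nearest spacer
    by Hamming distance is used, provided identity >= ``identity`` (<= 3
    mismatches over 20 nt), the nearest neighbour is unique, and the
    observed PAM (inside the target segment) matches the design's PAM
    class.  Ambiguous or too-distant reads stay unassigned.
    """
    by_spacer = {g.spacer: g for g in library}
    if len(by_spacer) != len(library):
        raise ValueError("library spacers must be unique")
    max_mm = int(round(SPACER_LEN * (1 - identity)))
    spacers = list(by_spacer)
    out = []
    for rec in records:
        guide = by_spacer.get(rec.spacer_obs)
        if guide is None:
            dists = [(_hamming(rec.spacer_obs, s), s) for s in spacers]
            best = min(d for d, _ in dists)
            hits = [s for d, s in dists if d == best]
            if best <= max_mm and len(hits) == 1:
                guide = by_spacer[hits[0]]
        if guide is not None:
            pam_len = PAM_LENGTHS.get(guide.pam_class, 0)
            pam_obs = rec.target_obs[
                target_upstream + SPACER_LEN : target_upstream + SPACER_LEN + pam_len
            ]
            pat = PAM_PATTERNS.get(guide.pam_class)
            if pat is None or not pat.fullmatch(pam_obs):
                guide = None
        rec.guide_id = guide.guide_id if guide is not None else None
        out.append(rec)
    return out


def call_edits(
    target_obs: str,
    reference_target: str,
    editor_class: str,
    window: tuple[int, int] = EDIT_WINDOW,
    target_upstream: int = 3,
    max_other_mismatch: int = 3,
) -> str:
    """Call the canonical editing outcome of one read.

    Returns an outcome key such as ``"5:C>T+6:C>T"`` enumerating window
    positions (1-based protospacer coordinates) carrying the editor's
    canonical transition (C->T for CBE, A->G for ABE on the protospacer
    strand), or ``"unedited"`` (no mismatch at all), or ``"other"``
    (mismatches but no canonical window transition).  A few non-canonical
    mismatches are sequencing/PCR noise handled by the background
    correction and do not alter the key; a read with more than
    ``max_other_mismatch`` of them is returned as ``"rejected"`` — its
    target does not plausibly derive from this reference (e.g. an
    undetected recombinant whose donor spacer resembles the host's) and
    it must not count toward the assigned depth.
    """
    if len(target_obs) != len(reference_target):
        raise ValueError("target length mismatch")
    ref_base = EDITOR_TARGET_BASE[editor_class]
    alt_base = EDITOR_ALT_BASE[editor_class]
    changes = []
    canonical_idx = set()
    for off in range(window[0], window[1] + 1):
        idx = target_upstream + off - 1
        if reference_target[idx] == ref_base and target_obs[idx] == alt_base:
            changes.append(f"{off}:{ref_base}>{alt_base}")
            canonical_idx.add(idx)
    n_other = sum(1 for i, (x, y) in enumerate(zip(target_obs, reference_target))
                  if x != y and i not in canonical_idx)
    if n_other > max_other_mismatch:
        return "rejected"
    if changes:
        return "+".join(changes)
    if n_other > 0:
        return "other"
    return "unedited"


def parse_outcome_key(key: str) -> list[tuple[int, str, str]]:
    """Outcome key -> list of (protospacer position, ref, alt)."""
    if key in ("unedited", "other"):
        return []
    out = []
    for part in key.split("+"):
        pos, change = part.split(":")
        ref, alt = change.split(">")
        out.append((int(pos), ref, alt))
    return out


def outcome_fraction(
    r_kj: Sequence[float],
    d_j: Sequence[float],
    h_c: float,
) -> float:
    """Background-corrected outcome fraction f_k averaged over samples.

    Samples with zero depth are excluded; raises if none remain.  The
    per-sample corrected value (R - D*h_c) / (D - D*h_c) is clamped to
    [0, 1] (the formula goes negative when the outcome is rarer in the
    edited sample than in controls).
    """
    if not 0 <= h_c < 1:
        raise ValueError("h_c must be in [0, 1)")
    vals = []
    for r, d in zip(r_kj, d_j):
        if d <= 0:
            continue
        vals.append(min(1.0, max(0.0, (r - d * h_c) / (d - d * h_c))))
    if not vals:
        raise ValueError("all samples have zero depth; f_k undefined")
    return float(np.mean(vals))


def tally_outcomes(
    records: Iterable[PairedReadRecord],
    library: Sequence[GuideDesign],
    refs: Mapping[str, str],
    sample_of_record: Mapping[str, str] | None = None,
    sample_ids: Sequence[str] | None = None,
    target_upstream: int = 3,
    target_len: int = 26,
) -> pd.DataFrame:
    """Per-guide, per-sample outcome tallies R_kj and depths D_j.

    ``sample_of_record`` maps read_id -> sample_id when records from several
    samples are pooled; otherwise all records belong to one sample "s1".
    Recombinant or unassigned records are dropped.  "other" reads (only
    non-canonical mismatches) count toward D_j but never toward any R_kj.
    Returns a long table (guide_id, sample_id, outcome_key, R, D).
    """
    by_id = {g.guide_id: g for g in library}
    ref_targets = {}
    for g in library:
        try:
            ref_targets[g.guide_id] = reference_target(g, refs, target_upstream, target_len)
        except ValueError:
            logger.warning("guide %s: no full-length target context; reads dropped",
                           g.guide_id)
    counts: dict[tuple[str, str, str], int] = {}
    depths: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.recombinant or rec.guide_id is None or rec.guide_id not in ref_targets:
            continue
        sample = sample_of_record.get(rec.read_id, "s1") if sample_of_record else "s1"
        g = by_id[rec.guide_id]
        key = call_edits(
            rec.target_obs, ref_targets[g.guide_id], g.editor_class,
            target_upstream=target_upstream,
        )
        if key == "rejected":
            continue
        depths[(g.guide_id, sample)] = depths.get((g.guide_id, sample), 0) + 1
        if key not in ("unedited", "other"):
            k = (g.guide_id, sample, key)
            counts[k] = counts.get(k, 0) + 1
    rows = []
    samples = sample_ids or sorted({s for _, s in depths})
    keys_per_guide: dict[str, set[str]] = {}
    for gid, _s, key in counts:
        keys_per_guide.setdefault(gid, set()).add(key)
    for gid, keys in keys_per_guide.items():
        for key in sorted(keys):
            for s in samples:
                rows.append({
                    "guide_id": gid,
                    "sample_id": s,
                    "outcome_key": key,
                    "R": counts.get((gid, s, key), 0),
                    "D": depths.get((gid, s), 0),
                })
    return pd.DataFrame(rows, columns=["guide_id", "sample_id", "outcome_key", "R", "D"])


def reference_target(
    guide: GuideDesign,
    refs: Mapping[str, str],
    target_upstream: int = 3,
    target_len: int = 26,
) -> str:
    """Unedited target segment for a guide, on the protospacer strand."""
    from becorr.guides import revcomp

    fwd = refs[guide.contig]
    if guide.strand == "+":
        start = guide.protospacer_start - target_upstream
        seg = fwd[start : start + target_len]
    else:
        end = guide.protospacer_start + SPACER_LEN + target_upstream
        seg = revcomp(fwd[end - target_len : end])
    if len(seg) != target_len:
        raise ValueError(f"target segment for {guide.guide_id} truncated by reference edge")
    return seg


def background_rates(control_tallies: pd.DataFrame) -> dict[tuple[str, str], float]:
    """h_c per (guide_id, outcome_key): mean control-sample fraction R/D.

    Outcome keys never seen in controls get h_c = 0 downstream.
    """
    rates: dict[tuple[str, str], float] = {}
    if control_tallies.empty:
        return rates
    for (gid, key), grp in control_tallies.groupby(["guide_id", "outcome_key"]):
        ok = grp["D"] > 0
        if ok.any():
            rates[(gid, key)] = float((grp.loc[ok, "R"] / grp.loc[ok, "D"]).mean())
    return rates


def corrected_fractions(
    edited_tallies: pd.DataFrame,
    h_c: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Apply the background correction to edited-sample tallies.

    Returns (guide_id, outcome_key, f_k, per-sample corrected fractions
    as f_<sample>) with clamping to [0, 1]; guides with zero depth in all
    edited samples are dropped.
    """
    rows = []
    for (gid, key), grp in edited_tallies.groupby(["guide_id", "outcome_key"]):
        h = h_c.get((gid, key), 0.0)
        ok = grp[grp["D"] > 0]
        if ok.empty:
            logger.warning("guide %s outcome %s has no covered edited sample", gid, key)
            continue
        per_sample = {}
        for row in ok.itertuples(index=False):
            per_sample[row.sample_id] = min(
                1.0, max(0.0, (row.R - row.D * h) / (row.D - row.D * h))
            )
        rec = {"guide_id": gid, "outcome_key": key, "h_c": h,
               "f_k": float(np.mean(list(per_sample.values())))}
        for s, v in per_sample.items():
            rec[f"f_{s}"] = v
        for row in grp.itertuples(index=False):
            rec[f"R_{row.sample_id}"] = row.R
            rec[f"D_{row.sample_id}"] = row.D
        rows.append(rec)
    return pd.DataFrame(rows)


def merge_and_pick_major(
    fractions: pd.DataFrame,
    annotations: pd.DataFrame,
    edited_samples: Sequence[str],
    min_coverage: int = MIN_COVERAGE,
    min_frequency: float = MIN_FREQUENCY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge outcomes at the amino-acid level and pick each guide's major one.

    ``fractions`` comes from :func:`corrected_fractions`; ``annotations``
    (guide_id, outcome_key, aa_changes, mutational_type, nucleotide_changes)
    from :mod:`becorr.annotate`.  Coding outcomes with identical amino-acid
    changes are merged (fractions and read support summed); noncoding
    outcomes merge only at identical nucleotide changes.  The major outcome
    is the merged group with the highest f_k; ties break by fewer edited
    positions then lexicographic key.  A guide passes the coverage filters
    unless its major outcome has read support < ``min_coverage`` or
    frequency < ``min_frequency`` in every edited replicate.

    Returns (outcomes table with is_major, efficiency table with q_raw).
    """
    ann = annotations.set_index(["guide_id", "outcome_key"])
    merged_rows = []
    eff_rows = []
    df = fractions.merge(annotations, on=["guide_id", "outcome_key"], how="left")
    df["aa_changes"] = df["aa_changes"].fillna("")
    df["mutational_type"] = df["mutational_type"].fillna("unannotated")
    df["nucleotide_changes"] = df["nucleotide_changes"].fillna("")

    for gid, grp in df.groupby("guide_id"):
        grp = grp.copy()
        grp["merge_key"] = np.where(
            grp["aa_changes"] != "", "aa:" + grp["aa_changes"],
            "nt:" + grp["nucleotide_changes"],
        )
        merged = []
        for mkey, sub in grp.groupby("merge_key"):
            rec = {
                "guide_id": gid,
                "merge_key": mkey,
                "outcome_key": "+".join(sorted(sub["outcome_key"])),
                "nucleotide_changes": ";".join(sorted(set(sub["nucleotide_changes"]))),
                "aa_changes": sub["aa_changes"].iloc[0],
                "mutational_type": _highest_priority(sub["mutational_type"]),
                "f_k": float(sub["f_k"].sum()),
                "n_positions": min(len(k.split("+")) for k in sub["outcome_key"]),
            }
            for s in edited_samples:
                fcol, rcol, dcol = f"f_{s}", f"R_{s}", f"D_{s}"
                rec[fcol] = float(sub[fcol].sum()) if fcol in sub else np.nan
                rec[rcol] = float(sub[rcol].sum()) if rcol in sub else 0.0
                rec[dcol] = float(sub[dcol].iloc[0]) if dcol in sub else 0.0
            merged.append(rec)
        merged.sort(key=lambda r: (-r["f_k"], r["n_positions"], r["outcome_key"]))
        for i, rec in enumerate(merged):
            rec["is_major"] = i == 0
            merged_rows.append(rec)
        major = merged[0]
        fails = []
        for s in edited_samples:
            cov = major.get(f"R_{s}", 0.0)
            freq = major.get(f"f_{s}", np.nan)
            fails.append(cov < min_coverage or (np.isnan(freq) or freq < min_frequency))
        eff_rows.append({
            "guide_id": gid,
            "major_outcome": major["outcome_key"],
            "aa_changes": major["aa_changes"],
            "mutational_type": major["mutational_type"],
            "q_raw": major["f_k"],
            "coverage": ";".join(str(int(major.get(f"R_{s}", 0))) for s in edited_samples),
            "depth": ";".join(str(int(major.get(f"D_{s}", 0))) for s in edited_samples),
            "passed_filters": not all(fails),
        })
    outcomes = pd.DataFrame(merged_rows)
    efficiency = pd.DataFrame(
        eff_rows,
        columns=["guide_id", "major_outcome", "aa_changes", "mutational_type",
                 "q_raw", "coverage", "depth", "passed_filters"],
    )
    return outcomes, efficiency


_TYPE_PRIORITY = ["stop_gain", "splicing", "nonsynonymous", "synonymous", "UTR",
                  "unannotated", "intergenic"]


def _highest_priority(types: Iterable[str]) -> str:
    ranked = sorted(types, key=lambda t: _TYPE_PRIORITY.index(t)
                    if t in _TYPE_PRIORITY else len(_TYPE_PRIORITY))
    return ranked[0] if ranked else "unannotated"
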
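"""Guide counting, control-anchored normalization and ln fold changes.

Raw sgRNA counts are normalized per sample by a constant w_j, the
geometric mean of the non-targeting (negative-control) guide counts in
that sample; the ln fold change of guide i in replicate j is re-centered
on the negative-control median:

    b_hat_j = median over negative controls of ln(C_kj / S_kj)
    d_ij    = ln(C_ij / S_ij) - b_hat_j

so that any per-sample depth rescaling cancels and the control median of
d is exactly zero.  A +1 pseudocount on raw counts keeps dropped-out
guides finite.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SPACER_LEN = 20


def count_guides(
    fastq_paths: Mapping[str, str],
    library: pd.DataFrame,
    mode: str = "scan",
    offset: int = 0,
) -> pd.DataFrame:
    """Count exact spacer matches per sample FASTQ.

    ``fastq_paths`` maps sample_id -> FASTQ path.  In ``offset`` mode the
    spacer is expected at a fixed position in the read; in ``scan`` mode
    every 20-mer of the read is tested.  A read increments at most one
    guide; reads matching no spacer (or, when scanning, more than one
    distinct spacer) are tallied as unmatched.
    """
    spacer_to_guide = dict(zip(library["spacer"], library["guide_id"]))
    if len(spacer_to_guide) != len(library):
        raise ValueError("library spacers must be unique")
    counts = pd.DataFrame(
        0, index=pd.Index(library["guide_id"], name="guide_id"),
        columns=list(fastq_paths),
    )
    for sample, path in fastq_paths.items():
        n_reads = n_unmatched = 0
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = str(rec.seq).upper()
            n_reads += 1
            if mode == "offset":
                gid = spacer_to_guide.get(seq[offset : offset + SPACER_LEN])
                hits = {gid} - {None}
            else:
                hits = {
                    spacer_to_guide[seq[i : i + SPACER_LEN]]
                    for i in range(len(seq) - SPACER_LEN + 1)
                    if seq[i : i + SPACER_LEN] in spacer_to_guide
                }
            if len(hits) == 1:
                counts.loc[next(iter(hits)), sample] += 1
            else:
                n_unmatched += 1
        if n_reads == 0:
            logger.warning("sample %s: empty FASTQ %s", sample, path)
        else:
            logger.info("sample %s: %d reads, %d unmatched", sample, n_reads, n_unmatched)
    return counts


class MedianRatioNormalizer:
    """Normalize counts by the geometric mean of negative-control guides.

    scikit-learn style transformer over a guide x sample count frame.

    Parameters
    ----------
    pseudocount : added to every raw count before both normalization and
        any downstream log, so control anchoring is preserved.

    Attributes
    ----------
    w_ : pd.Series
        Per-sample normalization constants (geometric mean of
        pseudocounted negative-control counts).
    negative_controls_ : list of guide ids used for anchoring.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def get_params(self, deep: bool = True) -> dict:
        return {"pseudocount": self.pseudocount}

    def set_params(self, **params) -> "MedianRatioNormalizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, counts: pd.DataFrame, negative_controls: Sequence[str]):
        negative_controls = [g for g in negative_controls if g in counts.index]
        if not negative_controls:
            raise ValueError("control-anchored normalization requires >=1 negative-control guide")
        sub = counts.loc[negative_controls] + self.pseudocount
        if (sub <= 0).any().any():
            raise ValueError("non-positive pseudocounted control counts")
        self.w_ = np.exp(np.log(sub).mean(axis=0))
        self.negative_controls_ = list(negative_controls)
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return (counts + self.pseudocount) / self.w_

    def fit_transform(self, counts: pd.DataFrame, negative_controls: Sequence[str]):
        return self.fit(counts, negative_controls).transform(counts)


def normalize(
    counts: pd.DataFrame,
    negative_controls: Sequence[str],
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Functional wrapper: returns (normalized counts, w_j)."""
    norm = MedianRatioNormalizer(pseudocount=pseudocount)
    out = norm.fit_transform(counts, negative_controls)
    return out, norm.w_


def compute_d(
    normalized: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    negative_controls: Sequence[str],
) -> pd.DataFrame:
    """Control-anchored ln fold changes per guide and replicate.

    ``sample_sheet`` needs columns sample_id, timepoint in {day0, dayN},
    replicate; each replicate must have exactly one sample per timepoint.
    Returns a long frame (guide_id, replicate, S, C, ln_fc, b_hat, d).
    """
    negative_controls = [g for g in negative_controls if g in normalized.index]
    if not negative_controls:
        raise ValueError("need >=1 negative-control guide for b_hat")
    rows = []
    for rep, grp in sample_sheet.groupby("replicate"):
        day0 = grp.loc[grp["timepoint"] == "day0", "sample_id"]
        dayn = grp.loc[grp["timepoint"] == "dayN", "sample_id"]
        if len(day0) != 1 or len(dayn) != 1:
            raise ValueError(f"replicate {rep}: need exactly one day0 and one dayN sample")
        S = normalized[day0.iloc[0]]
        C = normalized[dayn.iloc[0]]
        if (S <= 0).any() or (C <= 0).any():
            raise ValueError("normalized counts must be positive")
        ln_fc = np.log(C / S)
        b_hat = float(np.median(ln_fc.loc[negative_controls]))
        rows.append(pd.DataFrame({
            "guide_id": normalized.index,
            "replicate": rep,
            "S": S.values,
            "C": C.values,
            "ln_fc": ln_fc.values,
            "b_hat": b_hat,
            "d": ln_fc.values - b_hat,
        }))
    return pd.concat(rows, ignore_index=True)


def quantify(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize and compute fold changes in one step.

    Negative controls are the library's non_targeting guides; essential-stop
    controls are carried through as a QC class but never anchor the
    normalization.  Returns (fold-change table, w_j).
    """
    neg = library.loc[library["control_class"] == "non_targeting", "guide_id"].tolist()
    normalized, w = normalize(counts, neg, pseudocount)
    fc = compute_d(normalized, sample_sheet, neg)
    cls = dict(zip(library["guide_id"], library["control_class"]))
    fc["control_class"] = fc["guide_id"].map(cls).fillna("targeting")
    return fc, w
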
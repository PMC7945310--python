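"""sgRNA enumeration for base-editing saturation libraries.

A cytosine base editor (CBE) converts C->T and an adenine base editor (ABE)
converts A->G within an editing window spanning protospacer positions 4-8
(1 = PAM-distal end), equivalently 13-17 bp upstream of the PAM.  For every
targetable base on either strand of the supplied references we emit one
guide; when several protospacers place the base inside the window, the one
placing it farthest from the PAM (minimal target offset) is selected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SPACER_LEN = 20
EDIT_WINDOW = (4, 8)  # 1-based protospacer positions, inclusive

PAM_PATTERNS = {"NGG": re.compile(r"[ACGT]GG"), "NG": re.compile(r"[ACGT]G")}
PAM_LENGTHS = {"NGG": 3, "NG": 2}
EDITOR_TARGET_BASE = {"CBE": "C", "ABE": "A"}
EDITOR_ALT_BASE = {"CBE": "T", "ABE": "G"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GuideDesign:
    """One designed sgRNA with its intended target base.

    Coordinates are 0-based half-open on the forward strand of ``contig``;
    ``spacer`` and ``pam`` are given on the protospacer strand.
    ``target_offset`` is the 1-based protospacer position of the intended
    base (1 = PAM-distal end), constrained to the editing window 4-8.
    """

    guide_id: str
    spacer: str
    pam: str
    strand: str
    contig: str
    protospacer_start: int
    target_offset: int
    editor_class: str
    pam_class: str
    is_unique: bool = True
    control_class: str = "targeting"

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(self.spacer)}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (EDIT_WINDOW[0] <= self.target_offset <= EDIT_WINDOW[1]):
            raise ValueError(f"target_offset {self.target_offset} outside window {EDIT_WINDOW}")
        want = EDITOR_TARGET_BASE[self.editor_class]
        got = self.spacer[self.target_offset - 1]
        if got != want:
            raise ValueError(
                f"target base at offset {self.target_offset} is {got}, expected {want} "
                f"for {self.editor_class}"
            )
        if not PAM_PATTERNS[self.pam_class].fullmatch(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match class {self.pam_class}")


def read_references(fasta_path) -> dict[str, str]:
    """Read a FASTA file into ``{id: uppercase sequence}``."""
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not refs:
        raise ValueError(f"no sequences in {fasta_path}")
    for name, seq in refs.items():
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError(f"reference {name} contains non-ACGTN characters")
    return refs


def enumerate_guides(
    refs: Mapping[str, str],
    editor_class: str = "CBE",
    pam_class: str = "NGG",
) -> list[GuideDesign]:
    """Enumerate one guide per targetable base on both strands of ``refs``.

    A base is targetable when it is the editor's substrate (C for CBE, A for
    ABE, read on the protospacer strand) and lies at protospacer position
    4-8 of a 20-nt protospacer directly followed by a PAM of ``pam_class``.
    When several candidate protospacers cover the same base, the minimal
    target offset (base farthest 5' of the PAM) wins.  Distinct bases whose
    winning protospacers coincide are collapsed into a single guide record
    at the minimal offset, so guides are unique per
    (contig, protospacer_start, strand).

    Candidates containing N are skipped with a warning; references shorter
    than ``SPACER_LEN`` + PAM length yield no guides.
    """
    if editor_class not in EDITOR_TARGET_BASE:
        raise ValueError(f"editor_class must be one of {sorted(EDITOR_TARGET_BASE)}")
    if pam_class not in PAM_PATTERNS:
        raise ValueError(f"pam_class must be one of {sorted(PAM_PATTERNS)}")

    base = EDITOR_TARGET_BASE[editor_class]
    pam_len = PAM_LENGTHS[pam_class]
    pam_pat = PAM_PATTERNS[pam_class]
    lo, hi = EDIT_WINDOW

    # (contig, strand, base position on the scanned strand) -> best candidate
    best: dict[tuple[str, str, int], tuple[int, int]] = {}
    seqs: dict[tuple[str, str], str] = {}

    for contig, fwd in refs.items():
        for strand in "+-":
            seq = fwd if strand == "+" else revcomp(fwd)
            seqs[(contig, strand)] = seq
            n = len(seq)
            for start in range(0, n - SPACER_LEN - pam_len + 1):
                pam = seq[start + SPACER_LEN : start + SPACER_LEN + pam_len]
                if not pam_pat.fullmatch(pam):
                    continue
                proto = seq[start : start + SPACER_LEN]
                window = proto[lo - 1 : hi]
                if base not in window:
                    continue
                if "N" in proto or "N" in pam:
                    logger.warning(
                        "skipping candidate at %s:%d (%s): N in protospacer/PAM",
                        contig, start, strand,
                    )
                    continue
                for off in range(lo, hi + 1):
                    if proto[off - 1] != base:
                        continue
                    key = (contig, strand, start + off - 1)
                    if key not in best or off < best[key][1]:
                        best[key] = (start, off)

    # Collapse bases sharing a winning protospacer; keep the minimal offset.
    chosen: dict[tuple[str, str, int], int] = {}
    for (contig, strand, _pos), (start, off) in best.items():
        key = (contig, strand, start)
        if key not in chosen or off < chosen[key]:
            chosen[key] = off

    guides = []
    for (contig, strand, start), off in chosen.items():
        seq = seqs[(contig, strand)]
        proto = seq[start : start + SPACER_LEN]
        pam = seq[start + SPACER_LEN : start + SPACER_LEN + pam_len]
        if strand == "+":
            fwd_start = start
        else:
            fwd_start = len(seq) - start - SPACER_LEN
        guides.append(
            GuideDesign(
                guide_id=f"{contig}_{fwd_start + 1}{'f' if strand == '+' else 'r'}_{editor_class}",
                spacer=proto,
                pam=pam,
                strand=strand,
                contig=contig,
                protospacer_start=fwd_start,
                target_offset=off,
                editor_class=editor_class,
                pam_class=pam_class,
            )
        )
    guides.sort(key=lambda g: (g.contig, g.protospacer_start, g.strand))
    return guides


def filter_unique(
    guides: Iterable[GuideDesign],
    refs: Mapping[str, str],
    require_pam: bool = True,
) -> list[GuideDesign]:
    """Set ``is_unique`` by exact-match occurrence counting over ``refs``.

    A guide is unique when its 20-nt spacer occurs exactly once across both
    strands of the supplied references; with ``require_pam`` an occurrence
    only counts when followed by a PAM of the guide's class.  Mismatches are
    not tolerated (0-mismatch off-target criterion); the search space is
    exactly the sequences given.
    """
    strands = []
    for contig, fwd in refs.items():
        strands.append(fwd)
        strands.append(revcomp(fwd))

    out = []
    for g in guides:
        pam_len = PAM_LENGTHS[g.pam_class]
        pam_pat = PAM_PATTERNS[g.pam_class]
        count = 0
        for seq in strands:
            pos = seq.find(g.spacer)
            while pos != -1:
                if require_pam:
                    pam = seq[pos + SPACER_LEN : pos + SPACER_LEN + pam_len]
                    if len(pam) == pam_len and pam_pat.fullmatch(pam):
                        count += 1
                else:
                    count += 1
                pos = seq.find(g.spacer, pos + 1)
        out.append(replace(g, is_unique=(count == 1)))
    return out


LIBRARY_COLUMNS = [
    "guide_id", "contig", "protospacer_start", "strand", "spacer", "pam",
    "target_offset", "editor_class", "pam_class", "is_unique", "control_class",
]


def guides_to_frame(guides: Iterable[GuideDesign]) -> pd.DataFrame:
    """Guide library table; protospacer_start is emitted 1-based inclusive."""
    rows = []
    for g in guides:
        rows.append({
            "guide_id": g.guide_id,
            "contig": g.contig,
            "protospacer_start": g.protospacer_start + 1,
            "strand": g.strand,
            "spacer": g.spacer,
            "pam": g.pam,
            "target_offset": g.target_offset,
            "editor_class": g.editor_class,
            "pam_class": g.pam_class,
            "is_unique": g.is_unique,
            "control_class": g.control_class,
        })
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def frame_to_guides(df: pd.DataFrame) -> list[GuideDesign]:
    guides = []
    for row in df.itertuples(index=False):
        guides.append(
            GuideDesign(
                guide_id=row.guide_id,
                spacer=row.spacer,
                pam=row.pam,
                strand=row.strand,
                contig=row.contig,
                protospacer_start=int(row.protospacer_start) - 1,
                target_offset=int(row.target_offset),
                editor_class=row.editor_class,
                pam_class=row.pam_class,
                is_unique=bool(row.is_unique),
                control_class=row.control_class,
            )
        )
    return guides


def apply_control_annotations(df: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Merge a curated control-guide table (guide_id, spacer, control_class).

    Control guides absent from the designed library (e.g. non-targeting
    spacers with no genomic site) are appended with placeholder coordinates.
    """
    df = df.copy()
    known = dict(zip(controls["guide_id"], controls["control_class"]))
    df["control_class"] = [
        known.get(gid, cc) for gid, cc in zip(df["guide_id"], df["control_class"])
    ]
    extra = controls[~controls["guide_id"].isin(df["guide_id"])]
    rows = []
    for row in extra.itertuples(index=False):
        rows.append({
            "guide_id": row.guide_id,
            "contig": "*",
            "protospacer_start": 0,
            "strand": "+",
            "spacer": row.spacer,
            "pam": "NA",
            "target_offset": 0,
            "editor_class": "NA",
            "pam_class": "NA",
            "is_unique": True,
            "control_class": row.control_class,
        })
    if rows:
        df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return df
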
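"""Consequence annotation of editing outcomes against a transcript model.

A minimal, strand-aware re-implementation of the variant annotation needed
for base-editing outcomes: codon-level translation with the standard
genetic code and classification into mutational types with the priority
stop_gain > splicing > nonsynonymous > synonymous > UTR.  A change on the
intronic side within 2 bp of an exon-intron junction is splicing;
a change outside the transcript span is intergenic and excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from becorr.guides import revcomp

logger = logging.getLogger(__name__)

SPLICE_DISTANCE = 2


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a reference contig.

    ``exons`` are 0-based half-open intervals on the forward strand, sorted
    and non-overlapping; ``cds_start``/``cds_end`` delimit the coding span
    (0-based half-open, forward coordinates) and the spliced CDS length
    must be a multiple of 3.  ``strand`` is the transcribed strand.
    """

    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if b1 > a2:
                raise ValueError("exons overlap")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in translation order."""
        pos = [p for a, b in self.exons for p in range(a, b)
               if self.cds_start <= p < self.cds_end]
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_sequence(self, refs: Mapping[str, str]) -> str:
        fwd = refs[self.contig]
        bases = [fwd[p] for a, b in self.exons for p in range(a, b)
                 if self.cds_start <= p < self.cds_end]
        seq = "".join(bases)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq

    def region_of(self, pos: int) -> str:
        """One of cds / utr / splicing / intron / intergenic for a position."""
        lo, hi = self.span
        if pos < lo or pos >= hi:
            return "intergenic"
        for a, b in self.exons:
            if a <= pos < b:
                return "cds" if self.cds_start <= pos < self.cds_end else "utr"
        for a, b in self.exons:
            if 0 < a - pos <= SPLICE_DISTANCE or 0 < pos - (b - 1) <= SPLICE_DISTANCE:
                return "splicing"
        return "intron"


def transcripts_from_frame(df: pd.DataFrame) -> dict[str, TranscriptModel]:
    """Build models from a TSV-shaped table.

    Expected columns: gene, contig, strand, exon_start, exon_end, cds_start,
    cds_end with 1-based inclusive coordinates (one row per exon).
    """
    models = {}
    for gene, grp in df.groupby("gene"):
        exons = [(int(r.exon_start) - 1, int(r.exon_end)) for r in grp.itertuples()]
        models[gene] = TranscriptModel(
            gene=gene,
            contig=grp["contig"].iloc[0],
            strand=grp["strand"].iloc[0],
            exons=exons,
            cds_start=int(grp["cds_start"].iloc[0]) - 1,
            cds_end=int(grp["cds_end"].iloc[0]),
        )
    return models


def annotate_outcome(
    nucleotide_changes: Sequence[tuple[int, str, str]],
    model: TranscriptModel,
    refs: Mapping[str, str],
) -> tuple[list[tuple[int, str, str]], str]:
    """Amino-acid consequences and mutational type of one editing outcome.

    ``nucleotide_changes`` are (0-based forward position, ref, alt) on the
    reference strand.  All coding changes of the outcome are applied
    together before translation, so two substitutions in one codon yield
    the combined amino-acid change.  Returns (aa_changes, mutational_type)
    where aa_changes is a list of (1-based protein position, ref AA,
    alt AA).
    """
    fwd = refs[model.contig]
    cds_pos = model.cds_positions()
    index_of = {p: i for i, p in enumerate(cds_pos)}
    cds_ref = model.cds_sequence(refs)
    if len(cds_ref) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")

    regions = []
    cds_edits: dict[int, str] = {}
    for pos, ref, alt in nucleotide_changes:
        if fwd[pos] != ref:
            raise ValueError(f"reference mismatch at {model.contig}:{pos + 1}: "
                             f"expected {ref}, found {fwd[pos]}")
        region = model.region_of(pos)
        regions.append(region)
        if region == "intergenic":
            logger.warning("change at %s:%d outside transcript %s span",
                           model.contig, pos + 1, model.gene)
        elif region == "cds":
            i = index_of[pos]
            base = alt if model.strand == "+" else revcomp(alt)
            cds_edits[i] = base

    aa_changes: list[tuple[int, str, str]] = []
    coding_type = None
    if cds_edits:
        cds_alt = list(cds_ref)
        for i, b in cds_edits.items():
            cds_alt[i] = b
        cds_alt = "".join(cds_alt)
        prot_ref = str(Seq(cds_ref).translate())
        prot_alt = str(Seq(cds_alt).translate())
        for k, (ra, aa) in enumerate(zip(prot_ref, prot_alt)):
            if ra != aa:
                aa_changes.append((k + 1, ra, aa))
        if any(aa == "*" and ra != "*" for _, ra, aa in aa_changes):
            coding_type = "stop_gain"
        elif aa_changes:
            coding_type = "nonsynonymous"
        else:
            coding_type = "synonymous"

    # priority: stop gain > splicing > nonsynonymous > synonymous > UTR
    if coding_type == "stop_gain":
        mtype = "stop_gain"
    elif "splicing" in regions:
        mtype = "splicing"
    elif coding_type in ("nonsynonymous", "synonymous"):
        mtype = coding_type
    elif "utr" in regions:
        mtype = "UTR"
    elif "intron" in regions:
        mtype = "intron"
    else:
        mtype = "intergenic"
    return aa_changes, mtype


def format_aa_changes(aa_changes: Sequence[tuple[int, str, str]]) -> str:
    return ";".join(f"{ra}{pos}{aa}" for pos, ra, aa in aa_changes)


def format_nt_changes(changes: Sequence[tuple[int, str, str]]) -> str:
    """1-based display form, e.g. 'chr:101A>G'."""
    return ";".join(f"{pos + 1}{ref}>{alt}" for pos, ref, alt in changes)


def guide_changes_from_key(guide, outcome_key: str) -> list[tuple[int, str, str]]:
    """Map a protospacer-coordinate outcome key to forward-strand changes."""
    from becorr.outcomes import parse_outcome_key

    changes = []
    for off, ref, alt in parse_outcome_key(outcome_key):
        if guide.strand == "+":
            pos = guide.protospacer_start + off - 1
            changes.append((pos, ref, alt))
        else:
            pos = guide.protospacer_start + (20 - off)
            changes.append((pos, revcomp(ref), revcomp(alt)))
    return sorted(changes)
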
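import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from becorr.annotate import TranscriptModel
from becorr.guides import enumerate_guides, filter_unique
from becorr.outcomes import reference_target
from becorr.quant import quantify
from becorr.scoring import score_table
from becorr.simulate import ScreenSimConfig, simulate_screen

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def default_screen():
    """One simulated screen at default study conditions, fully scored."""
    cfg = ScreenSimConfig(seed=0)
    counts, sheet, truth, library = simulate_screen(cfg)
    fc, w = quantify(counts, sheet, library)
    eff = truth.loc[truth["control_class"] == "targeting", ["guide_id", "q"]]
    eff = eff.rename(columns={"q": "q_raw"}).assign(passed_filters=True)
    scores = score_table(fc, eff, activity_filter=0.2)
    return {"config": cfg, "counts": counts, "sheet": sheet, "truth": truth,
            "library": library, "fold_changes": fc, "scores": scores}


@pytest.fixture(scope="session")
def assay_library():
    """Guide library over many short unrelated contigs for read-level tests.

    One CBE/NGG guide per 60-nt contig; each contig carries a single-exon
    transcript with a 57-nt CDS starting at position 0.
    """
    rng = np.random.default_rng(2024)
    refs = {}
    guides = []
    transcripts = {}
    i = 0
    while len(guides) < 120 and i < 300:
        i += 1
        contig = f"c{i:03d}"
        seq = random_seq(rng, 60)
        # plant an editable C in the window and an NGG PAM
        proto_start = 10
        off = int(rng.integers(4, 9))
        s = list(seq)
        s[proto_start + off - 1] = "C"
        s[proto_start + 21] = "G"
        s[proto_start + 22] = "G"
        seq = "".join(s)
        cand = enumerate_guides({contig: seq}, "CBE", "NGG")
        cand = [g for g in cand if g.strand == "+" and g.protospacer_start == proto_start]
        if not cand:
            continue
        g = cand[0]
        try:
            reference_target(g, {contig: seq})
        except ValueError:
            continue
        refs[contig] = seq
        guides.append(g)
        transcripts[contig] = TranscriptModel(
            gene=contig, contig=contig, strand="+", exons=[(0, 60)],
            cds_start=0, cds_end=57,
        )
    guides = filter_unique(guides, refs)
    assert len(guides) >= 100
    return {"refs": refs, "guides": guides, "transcripts": transcripts}
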
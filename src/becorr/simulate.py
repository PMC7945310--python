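"""Synthetic base-editing screens and target-site assay reads.

The screen generator draws counts under the exponential growth model: a
guide's day-N abundance mixes edited cells (fraction p = q * l) growing
as e^{b + f} with unedited cells growing as e^{b},

    C = S [ p e^{b+f} + (1 - p) e^{b} ],

with multinomial sampling at fixed sequencing depth on both days.  The
read generator emulates the integrated target-site assay: each read is
spacer + scaffold + target, with truth-drawn editing outcomes in the
protospacer window, uniform substitution errors, a configured fraction of
recombinant molecules (spacer from one guide, target from another), and
unedited control samples carrying errors only.  Both generators return
their ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from becorr.guides import (
    EDITOR_ALT_BASE,
    EDITOR_TARGET_BASE,
    EDIT_WINDOW,
    SPACER_LEN,
    GuideDesign,
)
from becorr.outcomes import reference_target

# canonical single-guide RNA scaffold
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTC"
    "CGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTTTT"
)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class ScreenSimConfig:
    """Study conditions for a synthetic screen.

    Defaults describe a desk-scale saturation screen: 5,000 guides of
    which 10% are non-targeting controls and 15% carry deleterious
    variants with relative fitness e^f drawn uniformly from [0.3, 0.8];
    remaining targeting guides are neutral (f = 0).  Editing activity q is
    uniform on [0.05, 1], the experiment editing scale l = 1 and the
    growth factor b = 2 (about three population doublings); sequencing
    depth is 2,000 reads per guide per sample (10^7 total) over two
    replicates, matching the per-guide coverage of a typical screen.
    """

    n_guides: int = 5000
    frac_non_targeting: float = 0.10
    frac_deleterious: float = 0.15
    frac_advantageous: float = 0.0
    deleterious_exp_f: tuple[float, float] = (0.3, 0.8)
    advantageous_exp_f: tuple[float, float] = (1.1, 1.4)
    q_range: tuple[float, float] = (0.0, 1.0)
    growth_b: float = 2.0
    editing_scale_l: float = 1.0
    abundance_sigma: float = 0.3
    depth_day0: int = 10_000_000
    depth_dayn: int = 10_000_000
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        total = self.frac_non_targeting + self.frac_deleterious + self.frac_advantageous
        if total > 1 + 1e-9:
            raise ValueError("control/effect fractions exceed 1")
        if not 0 < self.editing_scale_l <= 1:
            raise ValueError("editing scale l must be in (0, 1]")
        if self.depth_day0 <= 0 or self.depth_dayn <= 0:
            raise ValueError("depths must be positive")


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic screen.

    Returns (counts, sample_sheet, truth, library):

    - counts: guide x sample raw integer counts ("day0_r1", "dayN_r1", ...)
    - sample_sheet: sample_id, timepoint, replicate
    - truth: guide_id, control_class, f, exp_f, q, p, beta_star with
      beta_star = l (e^f - 1)
    - library: guide_id, spacer (random unique 20-mers), control_class
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_guides
    n_nt = int(round(n * config.frac_non_targeting))
    n_del = int(round(n * config.frac_deleterious))
    n_adv = int(round(n * config.frac_advantageous))

    classes = np.array(["targeting"] * n, dtype=object)
    roles = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_nt]] = "non_targeting"
    roles[order[:n_nt]] = "non_targeting"
    roles[order[n_nt : n_nt + n_del]] = "deleterious"
    roles[order[n_nt + n_del : n_nt + n_del + n_adv]] = "advantageous"

    exp_f = np.ones(n)
    exp_f[roles == "deleterious"] = rng.uniform(
        *config.deleterious_exp_f, size=(roles == "deleterious").sum()
    )
    exp_f[roles == "advantageous"] = rng.uniform(
        *config.advantageous_exp_f, size=(roles == "advantageous").sum()
    )
    f = np.log(exp_f)
    q = rng.uniform(*config.q_range, size=n)
    q[roles == "non_targeting"] = 0.0
    p = q * config.editing_scale_l
    beta_star = config.editing_scale_l * (exp_f - 1.0)

    guide_ids = [f"g{i + 1:05d}" for i in range(n)]
    spacers = _random_unique_spacers(n, rng)
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    abundance /= abundance.sum()

    counts = {}
    sheet_rows = []
    for rep in range(1, config.n_replicates + 1):
        day0 = rng.multinomial(config.depth_day0, abundance)
        growth = p * np.exp(config.growth_b + f) + (1 - p) * np.exp(config.growth_b)
        mass = abundance * growth
        dayn = rng.multinomial(config.depth_dayn, mass / mass.sum())
        counts[f"day0_r{rep}"] = day0
        counts[f"dayN_r{rep}"] = dayn
        sheet_rows.append({"sample_id": f"day0_r{rep}", "timepoint": "day0", "replicate": rep})
        sheet_rows.append({"sample_id": f"dayN_r{rep}", "timepoint": "dayN", "replicate": rep})

    counts_df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    truth = pd.DataFrame({
        "guide_id": guide_ids,
        "control_class": classes,
        "role": roles,
        "f": f,
        "exp_f": exp_f,
        "q": q,
        "p": p,
        "beta_star": beta_star,
        "abundance": abundance,
    })
    library = pd.DataFrame({
        "guide_id": guide_ids,
        "spacer": spacers,
        "control_class": classes,
    })
    return counts_df, pd.DataFrame(sheet_rows), truth, library


def expected_ratio(p: np.ndarray, f: np.ndarray, b: float) -> np.ndarray:
    """Noise-free expected C/S under the growth model."""
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    return p * np.exp(b + f) + (1 - p) * np.exp(b)


def _random_unique_spacers(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out) + 10, SPACER_LEN))
        for row in batch:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


@dataclass
class ReadSimConfig:
    """Study conditions for the integrated target-site assay generator.

    Editing probabilities are Beta(1.2, 6)-distributed by default
    (median ~0.13, long right tail), emulating the low and highly variable
    per-guide editing typical of such assays; when a guide's window holds
    a second editable base, a ``co_edit_fraction`` of its edited reads
    carry both changes.  Substitution sequencing errors are uniform per
    base and recombinant molecules pair a spacer with another guide's
    target.
    """

    reads_per_guide: int = 1000
    error_rate: float = 0.001
    recombination_fraction: float = 0.05
    edit_prob_beta: tuple[float, float] = (1.2, 6.0)
    co_edit_fraction: float = 0.2
    n_edited_replicates: int = 2
    n_control_replicates: int = 2
    scaffold: str = DEFAULT_SCAFFOLD
    target_upstream: int = 3
    target_len: int = 26
    seed: int = 0
    edit_probs: Mapping[str, float] | None = None  # optional explicit per-guide truth


def simulate_target_reads(
    config: ReadSimConfig,
    library: Sequence[GuideDesign],
    refs: Mapping[str, str],
    transcripts: Mapping[str, "object"] | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate assay reads with known outcome truth.

    Returns (reads, truth): ``reads`` maps sample ids ("edited_r1", ...,
    "control_r1", ...) to lists of (read_id, sequence); ``truth`` has one
    row per guide with edit_prob, the major outcome key, q_true (expected
    fraction of reads carrying the major nucleotide outcome) and the
    co-edit key (empty when the window has a single editable base).  When
    ``transcripts`` (gene -> TranscriptModel) is given, truth also carries
    q_true_merged: the expected fraction after amino-acid-level merging,
    which equals edit_prob when the co-edit outcome translates to the same
    amino-acid change as the major outcome.
    """
    rng = np.random.default_rng(config.seed)
    guides = []
    targets = {}
    for g in library:
        try:
            targets[g.guide_id] = reference_target(
                g, refs, config.target_upstream, config.target_len)
            guides.append(g)
        except ValueError:
            continue  # no full-length target context at the reference edge
    if not guides:
        raise ValueError("no guide has full-length target context")

    truth_rows = []
    outcome_plan = {}
    for g in guides:
        ref_t = targets[g.guide_id]
        ref_base = EDITOR_TARGET_BASE[g.editor_class]
        alt_base = EDITOR_ALT_BASE[g.editor_class]
        editable = [off for off in range(EDIT_WINDOW[0], EDIT_WINDOW[1] + 1)
                    if ref_t[config.target_upstream + off - 1] == ref_base]
        if g.target_offset not in editable:
            raise ValueError(f"guide {g.guide_id}: target base not editable in its window")
        if config.edit_probs is not None:
            edit_prob = float(config.edit_probs[g.guide_id])
        else:
            edit_prob = float(rng.beta(*config.edit_prob_beta))
        major = ((g.target_offset, ref_base, alt_base),)
        others = [o for o in editable if o != g.target_offset]
        co_frac = config.co_edit_fraction if others else 0.0
        co = None
        if others:
            partner = min(others, key=lambda o: abs(o - g.target_offset))
            co = tuple(sorted([(g.target_offset, ref_base, alt_base),
                               (partner, ref_base, alt_base)]))
        outcome_plan[g.guide_id] = (edit_prob, major, co, co_frac)
        row = {
            "guide_id": g.guide_id,
            "edit_prob": edit_prob,
            "major_key": _key_of(major),
            "co_key": _key_of(co) if co else "",
            "co_edit_fraction": co_frac,
            "q_true": edit_prob * (1 - co_frac),
        }
        if transcripts is not None:
            row["q_true_merged"] = edit_prob if co is not None and _same_aa_outcome(
                g, _key_of(major), _key_of(co), transcripts, refs
            ) else row["q_true"]
        truth_rows.append(row)

    samples = [f"edited_r{j + 1}" for j in range(config.n_edited_replicates)] + \
              [f"control_r{j + 1}" for j in range(config.n_control_replicates)]
    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    n_guides = len(guides)
    for s in samples:
        edited_sample = s.startswith("edited")
        for gi, g in enumerate(guides):
            edit_prob, major, co, co_frac = outcome_plan[g.guide_id]
            ref_t = targets[g.guide_id]
            n_reads = config.reads_per_guide
            recomb = rng.random(n_reads) < config.recombination_fraction
            edited = (rng.random(n_reads) < edit_prob) if edited_sample else \
                np.zeros(n_reads, dtype=bool)
            co_draw = rng.random(n_reads) < co_frac
            for ri in range(n_reads):
                if recomb[ri]:
                    donor = guides[(gi + 1 + int(rng.integers(n_guides - 1))) % n_guides]
                    target = targets[donor.guide_id]
                    tag = f"R:{donor.guide_id}"
                else:
                    target = ref_t
                    tag = "N"
                    if edited[ri]:
                        changes = co if (co is not None and co_draw[ri]) else major
                        target = _apply_changes(target, changes, config.target_upstream)
                seq = g.spacer + config.scaffold + target
                if config.error_rate > 0:
                    seq = _add_errors(seq, config.error_rate, rng)
                # read id fields: sample:guide:index:N|R[:donor]
                rid = f"{s}:{g.guide_id}:{ri}:{tag}"
                reads[s].append((rid, seq))
    return reads, pd.DataFrame(truth_rows)


def _same_aa_outcome(guide, key_a: str, key_b: str, transcripts, refs) -> bool:
    """Whether two coding outcome keys translate to identical aa changes."""
    from becorr.annotate import annotate_outcome, guide_changes_from_key

    models = [t for t in transcripts.values() if t.contig == guide.contig]
    if not models:
        return False
    model = models[0]
    aa_a, _ = annotate_outcome(guide_changes_from_key(guide, key_a), model, refs)
    aa_b, _ = annotate_outcome(guide_changes_from_key(guide, key_b), model, refs)
    return bool(aa_a) and aa_a == aa_b


def _key_of(changes) -> str:
    return "+".join(f"{off}:{ref}>{alt}" for off, ref, alt in sorted(changes))


def _apply_changes(target: str, changes, target_upstream: int) -> str:
    out = list(target)
    for off, _ref, alt in changes:
        out[target_upstream + off - 1] = alt
    return "".join(out)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def counts_to_fastq(counts: pd.Series, library: pd.DataFrame, path) -> None:
    """Expand a screen count column into spacer-only reads (exact matches)."""
    spacer = dict(zip(library["guide_id"], library["spacer"]))
    with open(path, "w") as fh:
        i = 0
        for gid, c in counts.items():
            s = spacer[gid]
            for _ in range(int(c)):
                fh.write(f"@r{i}:{gid}\n{s}\n+\n{'I' * len(s)}\n")
                i += 1
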
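"""Rule-based GPI-anchoring motif scanner.

GPI-anchored proteins carry a loose C-terminal motif rather than a strict
consensus.  The scanner evaluates its four canonical elements at each
candidate ω site (the residue to which the glycolipid is amide-linked):

  (a) the ω residue has a small side chain — G, C, D, A, N or S;
  (b) ω+1 and ω+2 also have small side chains — G, A or S;
  (c) a spacer of more than 6 hydrophilic residues begins at ω+3
      (hydrophilic: Kyte–Doolittle hydropathy < 0);
  (d) the chain ends in a membrane-spanning hydrophobic stretch — at least
      8 consecutive residues of mean hydropathy ≥ +1.5 terminating at (or
      within a few residues of) the C-terminus.

A candidate's composite score is the mean of the four component scores
(each in [0, 1]); the classification is "anchored" only when every
component passes *and* the composite clears the threshold, so partial
matches cannot inflate the call.  This is a deliberately transparent
surrogate for the published prediction servers (Big-PI, FragAnchor,
PredGPI): it reproduces qualitative anchored / not-anchored calls, not
their numeric scores.

The truncation scan recomputes the best composite after removing C-terminal
residues one at a time, locating where in the tail the anchoring potential
lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SequenceRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "OMEGA_RESIDUES",
    "SMALL_RESIDUES",
    "find_omega_candidates",
    "score_gpi_motif",
    "GPIMotifScore",
    "best_motif_score",
    "truncation_scan",
    "TruncationScan",
    "classify_panel",
    "MIN_MOTIF_SPAN",
]

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

OMEGA_RESIDUES = set("GCDANS")
SMALL_RESIDUES = set("GAS")

# ω + (ω+1..2) + 7-residue spacer + 8-residue hydrophobic stretch
MIN_MOTIF_SPAN = 1 + 2 + 7 + 8


def find_omega_candidates(seq: SequenceRecord, search_window: int = 40) -> list[int]:
    """1-based positions of small-side-chain residues within the last
    ``search_window`` residues — the candidate ω sites."""
    s = seq.seq
    start = max(0, len(s) - search_window)
    return [i + 1 for i in range(start, len(s)) if s[i] in OMEGA_RESIDUES]


@dataclass
class GPIMotifScore:
    omega: int                       # 1-based residue index
    scores: dict = field(default_factory=dict)    # component -> [0,1]
    passes: dict = field(default_factory=dict)    # component -> bool
    composite: float = 0.0
    anchored: bool = False
    threshold: float = 0.8


def _terminal_hydrophobic_run(
    downstream: str,
    min_len: int,
    mean_cutoff: float,
    terminal_slack: int,
    scale: dict,
) -> int:
    """Length of the longest contiguous stretch with mean hydropathy ≥
    ``mean_cutoff`` that ends within ``terminal_slack`` residues of the
    C-terminus; 0 if none."""
    n = len(downstream)
    if n == 0:
        return 0
    kd = np.array([scale[a] for a in downstream])
    csum = np.concatenate([[0.0], np.cumsum(kd)])
    best = 0
    for end in range(max(0, n - 1 - terminal_slack), n):  # inclusive end idx
        for start in range(0, end + 1):
            length = end - start + 1
            if length <= best:
                continue
            mean = (csum[end + 1] - csum[start]) / length
            if mean >= mean_cutoff:
                best = length
    return best


def score_gpi_motif(
    seq: SequenceRecord,
    omega: int,
    scale: dict | None = None,
    spacer_window: int = 12,
    spacer_required: int = 7,     # "> 6 hydrophilic residues"
    tail_min_len: int = 8,
    tail_mean_kd: float = 1.5,
    terminal_slack: int = 3,
    threshold: float = 0.8,
) -> GPIMotifScore:
    """Evaluate the four GPI-motif elements at candidate ω position
    ``omega`` (1-based)."""
    scale = KYTE_DOOLITTLE if scale is None else scale
    s = seq.seq
    if not 1 <= omega <= len(s):
        raise ValueError(f"omega position {omega} outside sequence of length {len(s)}")
    i = omega - 1

    # (a) small ω residue
    a_score = 1.0 if s[i] in OMEGA_RESIDUES else 0.0

    # (b) ω+1, ω+2 small
    nxt = s[i + 1 : i + 3]
    b_score = (sum(r in SMALL_RESIDUES for r in nxt) / 2.0) if len(nxt) == 2 else (
        sum(r in SMALL_RESIDUES for r in nxt) / 2.0
    )

    # (c) hydrophilic spacer from ω+3
    spacer = s[i + 3 : i + 3 + spacer_window]
    n_hydrophilic = sum(scale[r] < 0 for r in spacer)
    c_score = min(n_hydrophilic, spacer_required) / spacer_required

    # (d) terminal hydrophobic stretch downstream of the spacer start
    downstream = s[i + 3 :]
    run = _terminal_hydrophobic_run(
        downstream, tail_min_len, tail_mean_kd, terminal_slack, scale
    )
    d_score = min(run, tail_min_len) / tail_min_len

    scores = {"omega": a_score, "omega_plus": b_score, "spacer": c_score, "tail": d_score}
    passes = {
        "omega": a_score == 1.0,
        "omega_plus": b_score == 1.0,
        "spacer": n_hydrophilic >= spacer_required,
        "tail": run >= tail_min_len,
    }
    composite = float(np.mean(list(scores.values())))
    anchored = all(passes.values()) and composite >= threshold
    return GPIMotifScore(
        omega=omega,
        scores=scores,
        passes=passes,
        composite=composite,
        anchored=anchored,
        threshold=threshold,
    )


def best_motif_score(
    seq: SequenceRecord, search_window: int = 40, **kwargs
) -> GPIMotifScore | None:
    """Highest-composite candidate within the search window (anchored
    candidates preferred); ``None`` when no ω candidate exists."""
    candidates = find_omega_candidates(seq, search_window)
    if not candidates:
        return None
    scored = [score_gpi_motif(seq, w, **kwargs) for w in candidates]
    return max(scored, key=lambda sc: (sc.anchored, sc.composite))


@dataclass
class TruncationScan:
    seq_id: str
    steps: np.ndarray      # residues removed from the C-terminus
    scores: np.ndarray     # best composite per truncation step

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.steps.shape != self.scores.shape:
            raise ValueError("steps/scores length mismatch")


def truncation_scan(
    seq: SequenceRecord,
    search_window: int = 40,
    max_steps: int | None = None,
    **kwargs,
) -> TruncationScan:
    """Best composite motif score as a function of successive one-residue
    truncation of the carboxy terminus (step 0 = full length)."""
    if len(seq) < MIN_MOTIF_SPAN:
        raise ValueError(f"sequence shorter than the minimal motif span ({MIN_MOTIF_SPAN})")
    n_steps = len(seq) - MIN_MOTIF_SPAN + 1
    if max_steps is not None:
        n_steps = min(n_steps, max_steps + 1)
    steps = np.arange(n_steps)
    scores = np.zeros(n_steps)
    for s in steps:
        sub = SequenceRecord(id=seq.id, seq=seq.seq[: len(seq) - s])
        best = best_motif_score(sub, search_window, **kwargs)
        scores[s] = 0.0 if best is None else best.composite
    return TruncationScan(seq_id=seq.id, steps=steps, scores=scores)


def classify_panel(
    seqs: list[SequenceRecord], search_window: int = 40, **kwargs
) -> pd.DataFrame:
    """Anchored / not-anchored calls for a panel of sequences.

    Returns one row per sequence: best ω position (or <NA>), composite
    score, per-component passes and the classification.  These are
    qualitative rule-engine calls, not prediction-server scores.
    """
    if not seqs:
        raise ValueError("empty sequence panel")
    rows = []
    for rec in seqs:
        best = best_motif_score(rec, search_window, **kwargs)
        if best is None:
            rows.append(
                {"id": rec.id, "omega": pd.NA, "composite": 0.0,
                 "anchored": False, "classification": "not_anchored"}
            )
        else:
            rows.append(
                {"id": rec.id, "omega": best.omega, "composite": best.composite,
                 "anchored": best.anchored,
                 "classification": "anchored" if best.anchored else "not_anchored"}
            )
    df = pd.DataFrame(rows).set_index("id")
    df.attrs["note"] = (
        "rule-based surrogate classification; numeric scores from external "
        "GPI prediction servers are out of scope"
    )
    return df
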
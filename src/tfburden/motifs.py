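"""PWM motif scoring and mutation-driven motif creation/disruption.

Scores are likelihood ratios: the product over motif positions of
p(base)/background(base), computed in log space, maximized over all windows
(both strands) — restricted to windows overlapping the mutation when
comparing alleles. A motif call is confident when the best score on either
allele clears an empirically calibrated threshold corresponding to a target
tail probability (default 1e-3) under the background model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import reverse_complement

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_EPSILON = 0.05
UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWM:
    """Per-position base-probability motif model with a scoring background."""

    motif_id: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = UNIFORM_BACKGROUND.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be width x 4")
        if self.width < 4:
            raise ValueError(f"motif width must be >= 4, got {self.width}")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("each matrix row must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id, counts, background=None,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "PWM":
        """Convert a count matrix (width x 4) to probabilities, adding the
        pseudocount split by background base frequencies."""
        counts = np.asarray(counts, dtype=float)
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        probs = counts + pseudocount * bg
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, matrix=probs, background=bg,
                   pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(self.background)


def read_jaspar_pwms(path, background=None,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read a JASPAR-format count-matrix file into PWMs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            out.append(
                PWM.from_counts(m.matrix_id or m.name, counts,
                                background=background, pseudocount=pseudocount)
            )
    return out


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-score of every window; NaN where the window contains N."""
    w = lo.shape[0]
    n_win = len(codes) - w + 1
    scores = np.full(n_win, np.nan)
    for start in range(n_win):
        window = codes[start : start + w]
        if (window < 0).any():
            continue
        scores[start] = lo[np.arange(w), window].sum()
    return scores


def pwm_score(sequence: str, pwm: PWM, scan_both_strands: bool = True,
              windows: slice | None = None):
    """Best likelihood-ratio window score over a sequence.

    Returns (score, offset, strand) where offset is the 0-based window start
    on the forward sequence. Windows containing N are skipped; an error is
    raised when no window is valid.
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than motif width {pwm.width}"
        )
    lo = pwm.log_odds()
    fwd = _window_scores(_encode(sequence), lo)
    n_win = len(fwd)
    if scan_both_strands:
        rev = _window_scores(_encode(reverse_complement(sequence)), lo)
        rev_aligned = rev[::-1]  # rev window j covers fwd window n_win-1-j
    else:
        rev_aligned = np.full(n_win, np.nan)
    if windows is not None:
        mask = np.zeros(n_win, dtype=bool)
        mask[windows] = True
        fwd = np.where(mask, fwd, np.nan)
        rev_aligned = np.where(mask, rev_aligned, np.nan)
    stacked = np.vstack([fwd, rev_aligned])
    if np.isnan(stacked).all():
        raise ValueError("no valid scoring window (N bases or empty restriction)")
    filled = np.where(np.isnan(stacked), -np.inf, stacked)  # NaN = skipped window
    flat = np.argmax(filled)
    strand_i, offset = divmod(int(flat), n_win)
    best = float(filled[strand_i, offset])
    return float(np.exp(best)), offset, "+" if strand_i == 0 else "-"


def calibrate_threshold(pwm: PWM, seq_length: int, p_target: float = 1e-3,
                        n_draws: int | None = None, seed: int | None = None,
                        background_model=None) -> float:
    """Empirical (1 - p_target) quantile of best-window scores on random
    sequences of the query length drawn from the background model."""
    if n_draws is None:
        n_draws = int(np.ceil(10 / p_target))
    if n_draws < 10 / p_target:
        raise ValueError(f"n_draws must be >= {10 / p_target:.0f} for p_target={p_target}")
    rng = np.random.default_rng(seed)
    probs = pwm.background if background_model is None else np.asarray(background_model, float)
    probs = probs / probs.sum()
    lo = pwm.log_odds()
    w = pwm.width
    draws = rng.choice(4, size=(n_draws, seq_length), p=probs)
    n_win = seq_length - w + 1
    best = np.full(n_draws, -np.inf)
    rows = np.arange(w)
    for start in range(n_win):
        window = draws[:, start : start + w]
        scores = lo[rows, window].sum(axis=1)
        np.maximum(best, scores, out=best)
        # reverse strand
        rc = 3 - window[:, ::-1]
        np.maximum(best, lo[rows, rc].sum(axis=1), out=best)
    return float(np.exp(np.quantile(best, 1 - p_target)))


@dataclass
class MotifShiftResult:
    motif_id: str
    score_ref: float
    score_mut: float
    score_ratio: float
    classification: str  # created | disrupted | unchanged
    mutation_offset_in_motif: int
    confident: bool

    @property
    def log_ratio(self) -> float:
        return float(np.log(self.score_ratio))


def motif_score_ratio(
    ref_seq: str,
    mut_seq: str,
    pwm_library,
    mutation_positions=None,
    epsilon: float = DEFAULT_EPSILON,
    thresholds: dict | None = None,
    p_target: float = 1e-3,
    calibration_draws: int | None = None,
    seed: int | None = None,
) -> list[MotifShiftResult]:
    """Score each motif on the reference and mutant alleles and classify the
    change.

    Only windows overlapping a mutation position are scored (the alleles are
    identical elsewhere). ratio = score_mut / score_ref; created when
    ratio > 1 + epsilon, disrupted when < 1 - epsilon, else unchanged.
    ``thresholds`` maps motif_id to a pre-calibrated confidence threshold;
    missing entries are calibrated on the fly at ``p_target``.
    """
    if len(ref_seq) != len(mut_seq):
        raise ValueError("ref and mut sequences must have identical length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_seq, mut_seq)) if a != b]
    if mutation_positions is None:
        mutation_positions = diffs
    else:
        mutation_positions = sorted(int(p) for p in mutation_positions)
        extra = set(diffs) - set(mutation_positions)
        if extra:
            raise ValueError(
                f"sequences differ outside the declared mutation positions: {sorted(extra)}"
            )
    if not mutation_positions:
        raise ValueError("no mutation position declared or observed")
    thresholds = dict(thresholds or {})
    results = []
    for pwm in pwm_library:
        w = pwm.width
        lo_start = max(0, min(mutation_positions) - w + 1)
        hi_start = min(len(ref_seq) - w, max(mutation_positions))
        if hi_start < lo_start:
            raise ValueError(f"sequence too short to scan motif {pwm.motif_id}")
        restriction = slice(lo_start, hi_start + 1)
        score_ref, off_ref, _ = pwm_score(ref_seq, pwm, windows=restriction)
        score_mut, off_mut, _ = pwm_score(mut_seq, pwm, windows=restriction)
        ratio = score_mut / score_ref
        if ratio > 1 + epsilon:
            classification = "created"
        elif ratio < 1 - epsilon:
            classification = "disrupted"
        else:
            classification = "unchanged"
        best_off = off_mut if score_mut >= score_ref else off_ref
        mut_offset = min(mutation_positions) - best_off
        if pwm.motif_id not in thresholds:
            thresholds[pwm.motif_id] = calibrate_threshold(
                pwm, seq_length=len(ref_seq), p_target=p_target,
                n_draws=calibration_draws, seed=seed,
            )
        confident = max(score_ref, score_mut) >= thresholds[pwm.motif_id]
        results.append(
            MotifShiftResult(
                motif_id=pwm.motif_id, score_ref=score_ref, score_mut=score_mut,
                score_ratio=ratio, classification=classification,
                mutation_offset_in_motif=int(mut_offset), confident=confident,
            )
        )
    results.sort(key=lambda r: abs(r.log_ratio), reverse=True)
    return results
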
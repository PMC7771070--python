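"""Occlusion attribution (HGT-Index) and palindrome significance tests.

The HGT-Index of a subsequence measures its contribution to the model's
prediction: with the sequence's baseline prediction l, the activations of
the first (stem) convolution whose receptive fields intersect the
subsequence are zeroed, giving an occluded prediction lᵢ, and
HIᵢ = |l − lᵢ|.  Stem output position j covers input positions
[j, j + kernel); occlusion zeroes every j whose coverage intersects the
interval, applied to the stem's post-BN/ReLU output so downstream layers
see genuine zeros.

Two significance tests ask whether DNA palindromes (inverted repeats, the
hallmark of transposon ends and REP elements) are important local
features:

* the *palindrome importance test* compares the HGT-Index of one randomly
  chosen palindromic subsequence per confidently-called positive sample
  against the HGT-Index of a random equal-length interval in the same
  sample;
* the *motif insertion test* splices a fixed palindromic motif (e.g. a
  REP-element inverted repeat) into random test sequences at random
  offsets and compares its effect on the prediction with that of splicing
  in random sequence of the same length, over many replicates.

Both report a two-sided independent-samples t-test (Student by default,
Welch behind a flag).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as sps

from .dataset import SampleSet
from .model import HgtClassifier, predict, youden_threshold
from .seq_core import DnaSequence, PalindromeMode, find_palindromes

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class OcclusionInterval:
    """A 0-based half-open interval on the model input sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class HgtIndexResult:
    baseline: float  # l, the unoccluded prediction
    occluded: float  # lᵢ, the prediction with the interval's stem output zeroed
    hi: float  # |l − lᵢ|


@dataclasses.dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    mean_treatment: float  # mean HGT-Index of the palindromic group
    mean_control: float  # mean HGT-Index of the random group
    n_treatment: int
    n_control: int
    threshold: Optional[float] = None  # operating threshold used for selection
    seed: Optional[int] = None

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def stem_mask_for_interval(
    interval: OcclusionInterval, input_length: int, kernel: int
) -> np.ndarray:
    """Boolean mask over stem positions whose receptive field intersects
    ``interval``: position j (covering input [j, j+kernel)) is masked iff
    j < end and j + kernel > start."""
    n_out = input_length - kernel + 1
    if interval.end > input_length:
        raise ValueError(f"interval [{interval.start}, {interval.end}) exceeds the input length")
    mask = np.zeros(n_out, dtype=bool)
    if len(interval) == 0:
        return mask
    lo = max(0, interval.start - kernel + 1)
    hi = min(n_out, interval.end)
    mask[lo:hi] = True
    return mask


def hgt_index(
    model: HgtClassifier, seq: "DnaSequence | str", interval: OcclusionInterval
) -> HgtIndexResult:
    """HGT-Index of one interval of one sequence (two forward passes)."""
    x = predict_input(model, seq)
    baseline = float(model.predict_proba(x)[0])
    mask = stem_mask_for_interval(interval, model.spec.input_length, model.spec.kernel_width)
    if not mask.any():
        return HgtIndexResult(baseline, baseline, 0.0)
    occluded = float(model.predict_proba(x, stem_mask=mask)[0])
    return HgtIndexResult(baseline, occluded, abs(baseline - occluded))


def predict_input(model: HgtClassifier, seq) -> np.ndarray:
    from .model import _as_onehot

    return _as_onehot([seq], model.spec.input_length)


def _ttest(treatment: np.ndarray, control: np.ndarray, welch: bool) -> tuple[float, float]:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(treatment, control, equal_var=not welch)
    if np.isnan(t) or np.isnan(p):
        warnings.warn("zero variance in both HGT-Index groups; reporting p = 1")
        return 0.0, 1.0
    return float(t), float(p)


def palindrome_importance_test(
    model: HgtClassifier,
    test_set: SampleSet,
    min_len: int = 10,
    mode: PalindromeMode = "center-gapped",
    seed: int = 0,
    welch: bool = False,
    labels: "np.ndarray | None" = None,
) -> TTestResult:
    """Are palindromic subsequences more important than random ones?

    Procedure: (1) pick the Youden operating threshold on the test set;
    (2) keep positive samples predicted above it that contain a maximal
    palindromic subsequence of length ≥ ``min_len``; (3) for each kept
    sample compute the HGT-Index of one uniformly chosen palindromic hit
    and of one uniformly chosen equal-length interval (palindromic or
    not); (4) two-sided t-test between the two HGT-Index collections.

    ``labels`` overrides the sample-set labels (useful for permutation
    controls).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    y = test_set.labels() if labels is None else np.asarray(labels, dtype=int)
    preds = predict(model, test_set)
    threshold = youden_threshold(preds, y)
    input_length = model.spec.input_length

    hi_palin, hi_null = [], []
    for i, sample in enumerate(test_set.samples):
        if y[i] != 1 or preds[i] <= threshold:
            continue
        hits = find_palindromes(sample.sequence, min_len=min_len, mode=mode)
        if not hits:
            continue
        hit = hits[int(rng.integers(0, len(hits)))]
        length = hit.length
        hi_palin.append(hgt_index(model, sample.sequence, OcclusionInterval(hit.start, hit.end)).hi)
        start0 = int(rng.integers(0, input_length - length + 1))
        hi_null.append(
            hgt_index(model, sample.sequence, OcclusionInterval(start0, start0 + length)).hi
        )
    if len(hi_palin) < 2:
        if np.ptp(preds) == 0:
            # a constant predictor qualifies nothing and carries no signal
            warnings.warn("constant predictions: the test is degenerate; reporting p = 1")
            return TTestResult(0.0, 1.0, 0.0, 0.0, 0, 0, threshold=float(threshold), seed=seed)
        raise ValueError(
            f"only {len(hi_palin)} qualifying samples (confident positives containing a "
            f"palindrome of ≥ {min_len} bp); need at least 2"
        )
    t, p = _ttest(np.array(hi_palin), np.array(hi_null), welch)
    return TTestResult(
        t, p, float(np.mean(hi_palin)), float(np.mean(hi_null)),
        len(hi_palin), len(hi_null), threshold=float(threshold), seed=seed,
    )


def motif_insertion_test(
    model: HgtClassifier,
    test_set: SampleSet,
    motif: "DnaSequence | str",
    n_reps: int = 5000,
    seed: int = 0,
    welch: bool = False,
    batch_size: int = 512,
) -> TTestResult:
    """Does splicing in a fixed motif shift predictions more than random
    sequence?

    Per replicate: draw a test sequence S (with replacement) with baseline
    prediction l and a uniform interval of the motif's length; replacing
    the interval with the motif gives l_palin, with a fresh uniformly
    random sequence gives l_null.  The two collections |l − l_palin| and
    |l − l_null| over ``n_reps`` replicates are compared by a two-sided
    t-test.
    """
    motif_s = motif.bases if isinstance(motif, DnaSequence) else str(motif).upper()
    input_length = model.spec.input_length
    if not 1 <= len(motif_s) <= input_length:
        raise ValueError(f"motif length must lie in [1, {input_length}]")
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    if len(test_set) == 0:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    base_preds = predict(model, test_set)
    m = len(motif_s)
    seqs = test_set.sequences()

    picks = rng.integers(0, len(seqs), size=n_reps)
    starts = rng.integers(0, input_length - m + 1, size=n_reps)
    spliced, randomized = [], []
    for k in range(n_reps):
        s = seqs[picks[k]]
        a = int(starts[k])
        rand = "".join("ACGT"[c] for c in rng.integers(0, 4, size=m))
        spliced.append(s[:a] + motif_s + s[a + m :])
        randomized.append(s[:a] + rand + s[a + m :])
    l_palin = predict(model, spliced, batch_size=batch_size)
    l_null = predict(model, randomized, batch_size=batch_size)
    l0 = base_preds[picks]
    t, p = _ttest(np.abs(l0 - l_palin), np.abs(l0 - l_null), welch)
    return TTestResult(
        t, p, float(np.mean(np.abs(l0 - l_palin))), float(np.mean(np.abs(l0 - l_null))),
        n_reps, n_reps, seed=seed,
    )


def hi_table(results: list[tuple[str, HgtIndexResult]], path: "str | Path") -> None:
    """Write per-sample HGT-Index rows as TSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {"id": name, "baseline": r.baseline, "occluded": r.occluded, "hgt_index": r.hi}
            for name, r in results
        ]
    ).to_csv(path, sep="\t", index=False)
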
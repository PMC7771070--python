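"""Sliding-window applications of a trained classifier.

Three procedures over raw reference or gene sequence:

* **genome likelihood** — mean predicted probability over 100 bp windows
  tiled at stride 50: the likelihood that a reference harbors insertion
  sites;
* **gene enrichment** — the same mean Ḡ over stride-10 windows of a gene
  region; a gene is flagged as enriched when Ḡ > 0.5 strictly;
* **hotspot detection** — per-nucleotide calls (the centered 100 bp
  window's prediction > 0.5 marks a potential insertion-site position),
  then windows of length l = 100 whose call rate r = n/l exceeds 0.2
  strictly are reported as hotspots.

Positions within 50 bp of a reference end carry no call (no padding);
hotspot windows count only defined called positions while keeping the
full window length in the denominator.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import HgtClassifier
from .seq_core import DnaSequence

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScanProfile:
    """Per-position predictions and calls over one reference."""

    ref_id: str
    positions: np.ndarray  # centers with a defined call: 50 … L−51
    predictions: np.ndarray  # Pᵢ for the window centered at each position
    calls: np.ndarray  # 1 iff Pᵢ > 0.5
    ref_length: int

    def to_tsv(self, path: "str | Path") -> None:
        pd.DataFrame(
            {"position": self.positions, "prediction": self.predictions, "call": self.calls}
        ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass(frozen=True)
class HotspotWindow:
    """A window whose insertion-site call rate r = n/l exceeds the cutoff."""

    ref_id: str
    start: int
    end: int
    n: int
    r: float


@dataclasses.dataclass(frozen=True)
class GeneScore:
    """Mean window prediction Ḡ over a gene and its enrichment flag."""

    gene_id: str
    g_bar: float
    enriched: bool
    n_windows: int


def _window_predictions(
    model: HgtClassifier, seq: DnaSequence, window: int, stride: int, batch_size: int = 512
) -> np.ndarray:
    length = len(seq)
    if length < window:
        raise ValueError(
            f"{seq.id}: length {length} is shorter than the {window} bp window"
        )
    starts = range(0, length - window + 1, stride)
    from .model import encode_sequences

    preds = np.empty(len(starts), dtype=np.float64)
    buf: list[str] = []
    lo = 0
    for s in starts:
        buf.append(seq.bases[s : s + window])
        if len(buf) == batch_size:
            preds[lo : lo + batch_size] = model.predict_proba(encode_sequences(buf, window))
            lo += batch_size
            buf = []
    if buf:
        preds[lo : lo + len(buf)] = model.predict_proba(encode_sequences(buf, window))
    return preds


def genome_likelihood(
    model: HgtClassifier, ref: DnaSequence, window: int = 100, stride: int = 50
) -> float:
    """Mean prediction over windows starting at 0, stride, 2·stride, …

    Trailing partial windows are dropped; a reference shorter than one
    window is an error.
    """
    return float(np.mean(_window_predictions(model, ref, window, stride)))


def gene_likelihood(
    model: HgtClassifier, gene: DnaSequence, window: int = 100, stride: int = 10
) -> Optional[GeneScore]:
    """Gene-level likelihood Ḡ and the strict Ḡ > 0.5 enrichment flag.

    Genes shorter than one window are reported unscored (``None``) with a
    warning.
    """
    if len(gene) < window:
        logger.warning(
            "gene %s (%d bp) is shorter than the %d bp window; left unscored",
            gene.id, len(gene), window,
        )
        return None
    preds = _window_predictions(model, gene, window, stride)
    g_bar = float(np.mean(preds))
    return GeneScore(gene.id, g_bar, g_bar > 0.5, preds.size)


def site_profile(
    model: HgtClassifier, ref: DnaSequence, window: int = 100, batch_size: int = 512
) -> ScanProfile:
    """Per-nucleotide insertion-site calls over a reference.

    For every position p ∈ [window/2, L − window/2) the window
    [p − 50, p + 50) centered on it is scored; the position is called
    when the prediction exceeds 0.5.
    """
    preds = _window_predictions(model, ref, window, stride=1, batch_size=batch_size)
    half = window // 2
    positions = np.arange(half, len(ref) - half)  # 50 … L−51 for the default window
    preds = preds[: positions.size]
    return ScanProfile(
        ref_id=ref.id,
        positions=positions,
        predictions=preds,
        calls=(preds > 0.5).astype(np.int8),
        ref_length=len(ref),
    )


def hotspot_windows(
    profile: ScanProfile, l: int = 100, r_min: float = 0.2, stride: int = 50
) -> list[HotspotWindow]:
    """Windows of length ``l`` whose call rate r = n/l strictly exceeds
    ``r_min``.

    Windows tile the reference at the given stride; those extending past
    the reference end are dropped.  Positions without a defined call
    contribute 0 to n while l stays in the denominator.
    """
    called = np.zeros(profile.ref_length, dtype=np.int8)
    called[profile.positions] = profile.calls
    out = []
    for start in range(0, profile.ref_length - l + 1, stride):
        n = int(called[start : start + l].sum())
        r = n / l
        if r > r_min:
            out.append(HotspotWindow(profile.ref_id, start, start + l, n, r))
    return out


def hotspots_to_bed(hotspots: Sequence[HotspotWindow], path: "str | Path") -> None:
    """Write hotspots as BED (0-based half-open; score = 1000·r)."""
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(f"{h.ref_id}\t{h.start}\t{h.end}\thotspot_n={h.n}\t{int(1000 * h.r)}\t.\n")


def gene_scores_to_tsv(scores: Sequence[Optional[GeneScore]], gene_ids: Sequence[str],
                       path: "str | Path") -> None:
    rows = []
    for gid, score in zip(gene_ids, scores):
        if score is None:
            rows.append({"gene_id": gid, "g_bar": "", "enriched": "", "n_windows": 0})
        else:
            rows.append(
                {
                    "gene_id": score.gene_id,
                    "g_bar": f"{score.g_bar:.6f}",
                    "enriched": int(score.enriched),
                    "n_windows": score.n_windows,
                }
            )
    pd.DataFrame(rows, columns=["gene_id", "g_bar", "enriched", "n_windows"]).to_csv(
        path, sep="\t", index=False
    )
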
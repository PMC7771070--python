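"""Dataset construction for insertion-site classification.

Turns reference sequences plus insertion-site tables into balanced,
split, optionally augmented sets of labeled 100-nt windows:

* positives are windows centered on an insertion site — the site junction
  sits between window offsets 49 and 50 (0-based, half-open coordinates
  throughout);
* negatives are windows whose centers lie at least ``min_dist`` (default
  10,000 bp) from every site on their reference, so positive and negative
  windows can never overlap;
* the set is randomly partitioned 80/10/10 into train/validation/test;
* training-time augmentation either shifts the sampling window by up to
  ±5 bp or substitutes up to 10 random bases, leaving labels unchanged.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seq_core import DnaSequence, one_hot_encode

logger = logging.getLogger(__name__)

WINDOW = 100

ORIGIN_POSITIVE = "positive"
ORIGIN_NEGATIVE = "negative"
ORIGIN_SHIFT = "augmented-shift"
ORIGIN_SUBSTITUTION = "augmented-substitution"

SPLITS = ("train", "validation", "test")


@dataclasses.dataclass(frozen=True)
class InsertionSite:
    """A labeled breakpoint junction on a named reference.

    ``position`` is the 0-based coordinate of the base immediately right of
    the junction.
    """

    ref_id: str
    position: int
    species: Optional[str] = None
    genus: Optional[str] = None


@dataclasses.dataclass
class LabeledSample:
    """A 100-nt window with a binary label and provenance."""

    sequence: DnaSequence
    label: int
    ref_id: str
    window_start: int
    origin: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


class SampleSet:
    """An ordered collection of :class:`LabeledSample` with split labels."""

    def __init__(self, samples: Sequence[LabeledSample], split: Optional[Sequence[str]] = None):
        self.samples = list(samples)
        if split is None:
            split = ["unsplit"] * len(self.samples)
        if len(split) != len(self.samples):
            raise ValueError("split must have one entry per sample")
        self.split = list(split)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def subset(self, split: str) -> "SampleSet":
        keep = [i for i, s in enumerate(self.split) if s == split]
        return SampleSet([self.samples[i] for i in keep], [split] * len(keep))

    def sequences(self) -> list[str]:
        return [s.sequence.bases for s in self.samples]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def one_hot(self) -> np.ndarray:
        """Stacked (N, 100, 4) float32 one-hot encoding."""
        return np.stack([one_hot_encode(s.sequence) for s in self.samples])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f"sample_{i}" for i in range(len(self))],
                "ref_id": [s.ref_id for s in self.samples],
                "window_start": [s.window_start for s in self.samples],
                "label": [s.label for s in self.samples],
                "origin": [s.origin for s in self.samples],
                "split": self.split,
                "sequence": self.sequences(),
            }
        )

    def to_tsv(self, path: "str | Path") -> None:
        """Serialize as TSV; a ``.gz`` suffix triggers gzip compression."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "SampleSet":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        samples = [
            LabeledSample(
                DnaSequence(str(r.id), r.sequence),
                int(r.label),
                str(r.ref_id),
                int(r.window_start),
                str(r.origin),
            )
            for r in df.itertuples()
        ]
        return cls(samples, [str(s) for s in df["split"]])


# ---------------------------------------------------------------------------
# site tables


def read_sites_tsv(path: "str | Path") -> list[InsertionSite]:
    """Read an insertion-site table (TSV with header).

    Expected columns: ``ref_id``, ``position`` (0-based), optionally
    ``species`` and ``genus``.
    """
    df = pd.read_csv(path, sep="\t")
    if "ref_id" not in df.columns or "position" not in df.columns:
        raise ValueError(f"{path}: site table needs 'ref_id' and 'position' columns")

    def _opt(row, col):
        if col in df.columns and pd.notna(getattr(row, col)):
            return str(getattr(row, col))
        return None

    return [
        InsertionSite(str(r.ref_id), int(r.position), _opt(r, "species"), _opt(r, "genus"))
        for r in df.itertuples()
    ]


def write_sites_tsv(sites: Iterable[InsertionSite], path: "str | Path") -> None:
    rows = [
        {
            "ref_id": s.ref_id,
            "position": s.position,
            "species": s.species if s.species is not None else "",
            "genus": s.genus if s.genus is not None else "",
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["ref_id", "position", "species", "genus"]).to_csv(
        path, sep="\t", index=False
    )


def _ref_map(refs: "Mapping[str, DnaSequence] | Sequence[DnaSequence]") -> dict[str, DnaSequence]:
    if isinstance(refs, Mapping):
        return dict(refs)
    return {r.id: r for r in refs}


# ---------------------------------------------------------------------------
# extraction


def extract_positive(
    ref: DnaSequence, site: InsertionSite, window: int = WINDOW
) -> Optional[LabeledSample]:
    """Extract the window centered on a site: ``[position − w/2, position + w/2)``.

    With the default window of 100 the junction sits between offsets 49 and
    50.  Sites closer than ``window/2`` to a reference end are skipped with
    a logged warning and ``None`` is returned.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    start = site.position - half
    end = site.position + half
    if start < 0 or end > len(ref):
        logger.warning(
            "site %s:%d too close to a reference end for a %d bp window; skipped",
            site.ref_id,
            site.position,
            window,
        )
        return None
    return LabeledSample(
        DnaSequence(f"{site.ref_id}:{start}-{end}", ref.bases[start:end]),
        1,
        site.ref_id,
        start,
        ORIGIN_POSITIVE,
    )


def extract_positives(
    refs: "Mapping[str, DnaSequence] | Sequence[DnaSequence]",
    sites: Sequence[InsertionSite],
    window: int = WINDOW,
) -> list[LabeledSample]:
    """Vector form of :func:`extract_positive`; unextractable sites are skipped."""
    refmap = _ref_map(refs)
    out = []
    for site in sites:
        if site.ref_id not in refmap:
            logger.warning("site on unknown reference %s skipped", site.ref_id)
            continue
        s = extract_positive(refmap[site.ref_id], site, window)
        if s is not None:
            out.append(s)
    return out


def eligible_negative_intervals(
    ref_len: int, site_positions: Sequence[int], min_dist: int = 10000, window: int = WINDOW
) -> list[tuple[int, int]]:
    """Half-open intervals of window *centers* eligible as negatives.

    A center c is eligible when the window fits (``half ≤ c ≤ L − half``)
    and ``|c − s| ≥ min_dist`` for every site s; exclusion zones of
    clustered sites are unioned.
    """
    half = window // 2
    lo, hi = half, ref_len - half + 1  # candidate centers [lo, hi)
    if hi <= lo:
        return []
    intervals = [(lo, hi)]
    for s in sorted(site_positions):
        banned = (s - min_dist + 1, s + min_dist)  # centers with |c-s| < min_dist
        nxt = []
        for a, b in intervals:
            if banned[1] <= a or banned[0] >= b:
                nxt.append((a, b))
                continue
            if a < banned[0]:
                nxt.append((a, banned[0]))
            if banned[1] < b:
                nxt.append((banned[1], b))
        intervals = nxt
        if not intervals:
            break
    return intervals


def sample_negatives(
    refs: "Mapping[str, DnaSequence] | Sequence[DnaSequence]",
    sites: Sequence[InsertionSite],
    n: int,
    min_dist: int = 10000,
    window: int = WINDOW,
    seed: int = 0,
) -> list[LabeledSample]:
    """Draw ``n`` distinct negative windows uniformly over eligible centers.

    Every returned window's center is ≥ ``min_dist`` from every site on its
    reference, so negatives never overlap positives.  Negative windows may
    overlap one another; duplicate centers are impossible (sampling is
    without replacement).  Deterministic under ``seed``.
    """
    refmap = _ref_map(refs)
    by_ref: dict[str, list[int]] = {rid: [] for rid in refmap}
    for s in sites:
        if s.ref_id in by_ref:
            by_ref[s.ref_id].append(s.position)

    spans = []  # (ref_id, center_start, center_end)
    for rid in sorted(refmap):
        for a, b in eligible_negative_intervals(len(refmap[rid]), by_ref[rid], min_dist, window):
            spans.append((rid, a, b))
    total = sum(b - a for _, a, b in spans)
    if total < n:
        raise ValueError(
            f"only {total} centers lie ≥ {min_dist} bp from every insertion site "
            f"(needed {n}); use longer references or fewer sites"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=n, replace=False)
    bounds = np.cumsum([b - a for _, a, b in spans])
    half = window // 2
    out = []
    for flat in picks:
        k = int(np.searchsorted(bounds, flat, side="right"))
        rid, a, _ = spans[k]
        offset = int(flat) - (int(bounds[k - 1]) if k else 0)
        center = a + offset
        start = center - half
        ref = refmap[rid]
        out.append(
            LabeledSample(
                DnaSequence(f"{rid}:{start}-{start + window}", ref.bases[start : start + window]),
                0,
                rid,
                start,
                ORIGIN_NEGATIVE,
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    sample_set: SampleSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SampleSet:
    """Randomly partition into train/validation/test.

    Validation and test sizes are the rounded fractions; the remainder goes
    to train.  Deterministic under ``seed``.
    """
    n = len(sample_set)
    if n == 0:
        raise ValueError("cannot split an empty sample set")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split fractions produce negative subset sizes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = ["train"] * n
    for i in order[n_train : n_train + n_val]:
        split[i] = "validation"
    for i in order[n_train + n_val :]:
        split[i] = "test"
    return SampleSet(sample_set.samples, split)


# ---------------------------------------------------------------------------
# augmentation


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def augment_shift(
    ref: DnaSequence,
    site: InsertionSite,
    max_shift: int = 5,
    seed=0,
    window: int = WINDOW,
) -> LabeledSample:
    """Positive window re-sampled with its start shifted by ±1..±max_shift.

    The shift is drawn uniformly from the nonzero offsets whose window
    still fits inside the reference; if none fits (or ``max_shift`` is 0)
    the canonical window is returned.
    """
    rng = _rng(seed)
    half = window // 2
    canonical = site.position - half
    valid = [
        d
        for d in range(-max_shift, max_shift + 1)
        if d != 0 and canonical + d >= 0 and canonical + d + window <= len(ref)
    ]
    if not valid:
        out = extract_positive(ref, site, window)
        if out is None:
            raise ValueError("site too close to a reference end for any window")
        return out
    start = canonical + int(rng.choice(valid))
    return LabeledSample(
        DnaSequence(f"{site.ref_id}:{start}-{start + window}", ref.bases[start : start + window]),
        1,
        site.ref_id,
        start,
        ORIGIN_SHIFT,
    )


def substitute_bases(bases: str, max_changes: int, rng: np.random.Generator) -> str:
    """Randomly change 1..max_changes positions to a different base.

    The number of changes is uniform on [1, max_changes], positions are
    drawn without replacement, and each changed position receives one of
    the three alternative bases.  ``max_changes = 0`` returns the input.
    """
    if max_changes <= 0:
        return bases
    n_changes = int(rng.integers(1, max_changes + 1))
    positions = rng.choice(len(bases), size=min(n_changes, len(bases)), replace=False)
    alphabet = "ACGT"
    chars = list(bases)
    for p in positions:
        current = chars[p]
        alternatives = [b for b in alphabet if b != current]
        chars[p] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def augment_substitute(sample: LabeledSample, max_changes: int = 10, seed=0) -> LabeledSample:
    """Copy of ``sample`` with up to ``max_changes`` random base substitutions.

    The label is preserved; label-1 outputs carry the
    ``augmented-substitution`` origin.
    """
    rng = _rng(seed)
    mutated = substitute_bases(sample.sequence.bases, max_changes, rng)
    origin = ORIGIN_SUBSTITUTION if sample.label == 1 else sample.origin
    return LabeledSample(
        DnaSequence(sample.sequence.id, mutated),
        sample.label,
        sample.ref_id,
        sample.window_start,
        origin,
    )


class TrainingAugmenter:
    """On-the-fly per-epoch augmentation of training windows.

    Each epoch, every training sample is independently left unchanged,
    window-shifted by up to ±``max_shift`` bp (when its reference is
    available), or perturbed by up to ``max_changes`` base substitutions.
    Both classes are augmented; labels never change.  Augmented sequences
    are ephemeral — the stored sample set is untouched.
    """

    def __init__(
        self,
        refs: "Mapping[str, DnaSequence] | Sequence[DnaSequence] | None" = None,
        max_shift: int = 5,
        max_changes: int = 10,
        p_shift: float = 1 / 3,
        p_substitute: float = 1 / 3,
    ):
        self.refs = _ref_map(refs) if refs is not None else {}
        self.max_shift = max_shift
        self.max_changes = max_changes
        self.p_shift = p_shift
        self.p_substitute = p_substitute

    def augment_epoch(self, samples: Sequence[LabeledSample], rng: np.random.Generator) -> list[str]:
        """Return one augmented sequence string per sample."""
        out = []
        for s in samples:
            u = rng.random()
            if u < self.p_shift and s.ref_id in self.refs and self.max_shift > 0:
                ref = self.refs[s.ref_id]
                w = len(s.sequence)
                valid_lo = max(-self.max_shift, -s.window_start)
                valid_hi = min(self.max_shift, len(ref) - w - s.window_start)
                choices = [d for d in range(valid_lo, valid_hi + 1) if d != 0]
                if choices:
                    start = s.window_start + int(rng.choice(choices))
                    out.append(ref.bases[start : start + w])
                    continue
                out.append(s.sequence.bases)
            elif u < self.p_shift + self.p_substitute and self.max_changes > 0:
                out.append(substitute_bases(s.sequence.bases, self.max_changes, rng))
            else:
                out.append(s.sequence.bases)
        return out


# ---------------------------------------------------------------------------
# composition summary


@dataclasses.dataclass
class CompositionSummary:
    """Percentage distribution of samples over a taxonomic rank."""

    table: pd.DataFrame  # columns: label, count, percentage (sorted descending)
    std_percent: float  # population standard deviation of the percentages
    n_missing: int  # records without a label at the requested rank


def composition_summary(records, rank: str = "species") -> CompositionSummary:
    """Tabulate the percentage distribution of labels at a taxonomic rank.

    ``records`` may be plain strings or objects carrying a ``species`` /
    ``genus`` attribute (e.g. :class:`InsertionSite`).  Records with a
    missing label are excluded and counted in ``n_missing``.
    """
    if rank not in ("species", "genus"):
        raise ValueError("rank must be 'species' or 'genus'")
    labels = []
    missing = 0
    for r in records:
        value = r if isinstance(r, str) else getattr(r, rank, None)
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            missing += 1
        else:
            labels.append(str(value))
    if not labels:
        raise ValueError(f"no records carry a {rank} label")
    counts = pd.Series(labels).value_counts()
    pct = 100.0 * counts / counts.sum()
    table = pd.DataFrame({"label": counts.index, "count": counts.values, "percentage": pct.values})
    if missing:
        logger.warning("%d records without a %s label were excluded", missing, rank)
    return CompositionSummary(table, float(np.std(pct.values)), missing)
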
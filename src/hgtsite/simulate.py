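"""Synthetic references with planted insertion-site signatures.

Transposon ends — the dominant agents of horizontal gene transfer — carry
characteristic local sequence features: inverted repeats (DNA palindromes)
and AT-rich stretches.  The generator emulates exactly that structure so
the whole pipeline is testable without any sequencing data:

* references are i.i.d. background sequence with configurable base
  frequencies;
* each truth site gets a planted signature centered on the junction: a
  random arm of ``arm_length`` bases immediately left of the site and its
  reverse complement immediately right (a strict palindrome of twice the
  arm length), each base independently corrupted with probability
  ``corruption`` (a degenerate inverted repeat), with the 10 bp flanking
  the repeat on each side AT-enriched;
* truth sites are emitted as a TSV table and positives/negatives are cut
  from the references with the same rules used for real site tables.

All randomness flows from one integer seed through per-reference
substreams, so regeneration is bit-exact.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .seq_core import DnaSequence

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in channel order


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Geometry and signature model of the synthetic benchmark.

    Defaults give a desk-scale benchmark: 6 references of 120 kb with 40
    planted sites each, palindromic arms of 5–10 bp, 5% per-base arm
    corruption and 70% AT-enrichment of the 10 bp flanks.
    """

    n_refs: int = 6
    ref_length: int = 120_000
    sites_per_ref: int = 40
    arm_length_range: tuple[int, int] = (5, 10)
    corruption: float = 0.05
    at_prob: float = 0.7
    flank: int = 10
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    site_spacing: int = 200
    species_labels: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.corruption <= 1 and 0 <= self.at_prob <= 1):
            raise ConfigError("corruption and at_prob must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ConfigError("background frequencies must be nonnegative and sum to 1")
        lo, hi = self.arm_length_range
        if not (1 <= lo <= hi):
            raise ConfigError("arm_length_range must satisfy 1 ≤ lo ≤ hi")
        if self.ref_length < 100:
            raise ConfigError("ref_length must be at least one window (100 bp)")
        if self.site_spacing < 2 * (hi + self.flank):
            raise ConfigError("site_spacing too small for the signature footprint")
        margin = 50
        needed = margin + self.sites_per_ref * self.site_spacing + margin
        if self.sites_per_ref > 0 and needed > self.ref_length:
            raise ConfigError(
                f"ref_length {self.ref_length} too small for {self.sites_per_ref} sites "
                f"at spacing {self.site_spacing} (needs ≥ {needed})"
            )
        if self.species_labels is not None and len(self.species_labels) != self.n_refs:
            raise ConfigError("species_labels must have one entry per reference")


def _random_bases(rng: np.random.Generator, n: int, background) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(background, dtype=float))


def _plant_signature(
    codes: np.ndarray, position: int, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Write one corrupted inverted repeat + AT-rich flanks around ``position``."""
    lo, hi = cfg.arm_length_range
    arm_len = int(rng.integers(lo, hi + 1))
    arm = _random_bases(rng, arm_len, cfg.background)
    left = arm
    right = _COMPLEMENT_IDX[arm[::-1]]  # reverse complement → strict palindrome
    repeat = np.concatenate([left, right])
    corrupt = rng.random(repeat.size) < cfg.corruption
    if corrupt.any():
        # shift by 1..3 mod 4 guarantees a different base
        repeat = repeat.copy()
        repeat[corrupt] = (repeat[corrupt] + rng.integers(1, 4, size=int(corrupt.sum()))) % 4
    codes[position - arm_len : position + arm_len] = repeat
    for flank_lo, flank_hi in (
        (position - arm_len - cfg.flank, position - arm_len),
        (position + arm_len, position + arm_len + cfg.flank),
    ):
        flank_lo = max(flank_lo, 0)
        flank_hi = min(flank_hi, codes.size)
        span = flank_hi - flank_lo
        if span <= 0:
            continue
        enrich = rng.random(span) < cfg.at_prob
        at = rng.choice([0, 3], size=span)  # A or T
        codes[flank_lo:flank_hi][enrich] = at[enrich]


def simulate_references(
    config: SimulationConfig,
) -> tuple[list[DnaSequence], list[ds.InsertionSite]]:
    """Generate references and their truth insertion-site table.

    Sites are laid on a jittered grid starting 50 bp into each reference
    with pitch ``site_spacing``, so every positive window fits and
    signatures never overlap; the remainder of each reference is
    signature-free territory for negative sampling.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_refs)
    refs: list[DnaSequence] = []
    sites: list[ds.InsertionSite] = []
    margin = 50
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        ref_id = f"simref_{i + 1}"
        species = (
            str(config.species_labels[i]) if config.species_labels is not None else "simulated"
        )
        codes = _random_bases(rng, config.ref_length, config.background)
        jitter_max = max(1, config.site_spacing // 4)
        for k in range(config.sites_per_ref):
            pos = margin + k * config.site_spacing + int(rng.integers(0, jitter_max))
            if pos >= config.ref_length - margin:
                break
            _plant_signature(codes, pos, config, rng)
            sites.append(ds.InsertionSite(ref_id, pos, species=species, genus=species))
        refs.append(DnaSequence(ref_id, _BASES[codes].tobytes().decode("ascii")))
    return refs, sites


def simulate_labeled_set(
    config: SimulationConfig,
    n_pos: int,
    n_neg: int,
    min_dist: int = 10000,
    window: int = 100,
) -> tuple[ds.SampleSet, list[DnaSequence], list[ds.InsertionSite]]:
    """Simulate references and cut a labeled window set from them.

    Positives are the windows centered on the first ``n_pos`` truth sites;
    negatives are background windows ≥ ``min_dist`` from every site (drawn
    by :func:`hgtsite.dataset.sample_negatives`).  Returns the (unsplit)
    sample set together with the references and truth sites it came from.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be ≥ 0")
    refs, sites = simulate_references(config)
    if len(sites) < n_pos:
        raise ConfigError(
            f"configuration plants only {len(sites)} sites but {n_pos} positives "
            "were requested; raise n_refs or sites_per_ref"
        )
    positives = ds.extract_positives(refs, sites[:n_pos], window)
    negatives = (
        ds.sample_negatives(refs, sites, n_neg, min_dist, window, seed=config.seed + 1)
        if n_neg
        else []
    )
    return ds.SampleSet(positives + negatives), refs, sites


def planted_config_for(n_pos: int, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` sized to plant at least ``n_pos`` sites.

    Convenience for benchmark construction: picks n_refs/sites_per_ref and
    a reference length that leaves ample ≥10 kb-from-site territory for an
    equal number of negatives.
    """
    sites_per_ref = overrides.pop("sites_per_ref", 500)
    n_refs = int(np.ceil(n_pos / sites_per_ref))
    spacing = overrides.pop("site_spacing", 200)
    ref_length = overrides.pop(
        "ref_length", 100 + sites_per_ref * spacing + 10_000 + max(40_000, n_pos // n_refs * 4)
    )
    return SimulationConfig(
        n_refs=n_refs,
        ref_length=ref_length,
        sites_per_ref=sites_per_ref,
        site_spacing=spacing,
        **overrides,
    )
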
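"""Connectome support of a GM-region / WM-tract pattern.

A significant latent component names a set of GM regions and WM tracts; this
module asks whether those regions are directly connected *through* those
tracts more strongly than chance. Input is a streamline-bundle summary table
(endpoint region pair, traversed tract labels, SIFT2-like total weight) —
tractogram reconstruction happens upstream. The observed statistic is the
total weight of bundles with both endpoints in the region set and at least
one traversed tract in the tract set (each bundle counted once); the null
redraws size-matched random region and tract sets uniformly from the label
universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError

__all__ = ["BundleTable", "PatternTestResult", "pattern_weight", "random_pattern_null"]


@dataclass
class BundleTable:
    """Streamline-bundle summaries over declared region/tract label universes."""

    frame: pd.DataFrame  # columns: region_a, region_b, tracts (tuple), weight
    region_universe: list
    tract_universe: list
    # incidence caches built lazily for the permutation null
    _region_idx: Optional[np.ndarray] = field(default=None, repr=False)
    _tract_inc: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.frame) == 0:
            raise ValidationError("empty bundle table")
        req = {"region_a", "region_b", "tracts", "weight"}
        if not req.issubset(self.frame.columns):
            raise ValidationError(f"bundle table needs columns {sorted(req)}")
        if (self.frame["weight"] < 0).any():
            raise ValidationError("bundle weights must be >= 0")
        runi, tuni = set(self.region_universe), set(self.tract_universe)
        for col in ("region_a", "region_b"):
            unknown = set(self.frame[col]) - runi
            if unknown:
                raise ValidationError(f"unknown region labels: {sorted(unknown)[:5]}")
        for tr in self.frame["tracts"]:
            unknown = set(tr) - tuni
            if unknown:
                raise ValidationError(f"unknown tract labels: {sorted(unknown)[:5]}")

    @classmethod
    def from_records(cls, rows: Sequence[tuple], region_universe, tract_universe):
        frame = pd.DataFrame(
            rows, columns=["region_a", "region_b", "tracts", "weight"]
        )
        frame["tracts"] = frame["tracts"].apply(tuple)
        return cls(frame, list(region_universe), list(tract_universe))

    # -- TSV dialect: regionA, regionB, tracts (semicolon-joined), weight ----

    @classmethod
    def from_tsv(cls, path, region_universe=None, tract_universe=None):
        df = pd.read_csv(path, sep="\t")
        rows = [
            (r.region_a, r.region_b, tuple(str(r.tracts).split(";")), float(r.weight))
            for r in df.itertuples()
        ]
        if region_universe is None:
            region_universe = sorted(set(df["region_a"]) | set(df["region_b"]))
        if tract_universe is None:
            tract_universe = sorted({t for row in rows for t in row[2]})
        return cls.from_records(rows, region_universe, tract_universe)

    def to_tsv(self, path):
        out = self.frame.copy()
        out["tracts"] = out["tracts"].apply(";".join)
        out.to_csv(path, sep="\t", index=False)

    # -- incidence structures ------------------------------------------------

    def _build_incidence(self):
        r_pos = {r: i for i, r in enumerate(self.region_universe)}
        t_pos = {t: i for i, t in enumerate(self.tract_universe)}
        n = len(self.frame)
        self._region_idx = np.column_stack(
            [
                self.frame["region_a"].map(r_pos).to_numpy(),
                self.frame["region_b"].map(r_pos).to_numpy(),
            ]
        )
        inc = np.zeros((n, len(self.tract_universe)), dtype=bool)
        for i, tr in enumerate(self.frame["tracts"]):
            for t in tr:
                inc[i, t_pos[t]] = True
        self._tract_inc = inc

    def incidence(self):
        if self._region_idx is None:
            self._build_incidence()
        return self._region_idx, self._tract_inc, self.frame["weight"].to_numpy(float)


def pattern_weight(bundles: BundleTable, regions, tracts) -> float:
    """Total weight of bundles captured by a (region set, tract set) pattern.

    A bundle counts (once) iff BOTH endpoints lie in ``regions`` AND at least
    one traversed tract is in ``tracts``. Monotone non-decreasing in both
    sets.
    """
    regions, tracts = set(regions), set(tracts)
    unknown = regions - set(bundles.region_universe)
    if unknown:
        raise ValidationError(f"unknown region label: {sorted(unknown)[0]!r}")
    unknown = tracts - set(bundles.tract_universe)
    if unknown:
        raise ValidationError(f"unknown tract label: {sorted(unknown)[0]!r}")
    if not regions or not tracts:
        return 0.0
    r_pos = {r: i for i, r in enumerate(bundles.region_universe)}
    t_pos = {t: i for i, t in enumerate(bundles.tract_universe)}
    ridx, tinc, w = bundles.incidence()
    rmask = np.zeros(len(bundles.region_universe), dtype=bool)
    rmask[[r_pos[r] for r in regions]] = True
    tmask = np.zeros(len(bundles.tract_universe), dtype=bool)
    tmask[[t_pos[t] for t in tracts]] = True
    hit = rmask[ridx[:, 0]] & rmask[ridx[:, 1]] & (tinc @ tmask)
    return float(w[hit].sum())


@dataclass
class PatternTestResult:
    """Observed pattern weight against a size-matched random-pattern null."""

    observed: float
    null_weights: np.ndarray
    p_value: float
    n_regions: int
    n_tracts: int
    n_permutations: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_regions": self.n_regions,
            "n_tracts": self.n_tracts,
            "n_permutations": self.n_permutations,
            "null_mean": float(self.null_weights.mean()),
            "null_sd": float(self.null_weights.std(ddof=1))
            if len(self.null_weights) > 1
            else None,
        }


def random_pattern_null(
    bundles: BundleTable,
    regions,
    tracts,
    n_permutations: int = 10_000,
    seed: Optional[int] = 0,
) -> PatternTestResult:
    """One-sided enrichment test of a pattern's direct connectivity.

    Draws ``n_permutations`` random patterns with the same number of regions
    and tracts as the observed one (both sets redrawn uniformly without
    replacement per draw) and computes p = (1 + #{null >= observed}) /
    (n_permutations + 1); high weight = enriched.
    """
    regions, tracts = sorted(set(regions)), sorted(set(tracts))
    B = int(n_permutations)
    if B < 1:
        raise ConfigError("n_permutations must be >= 1")
    nR, nT = len(bundles.region_universe), len(bundles.tract_universe)
    if len(regions) > nR or len(tracts) > nT:
        raise ConfigError("pattern larger than label universe")
    observed = pattern_weight(bundles, regions, tracts)
    ridx, tinc, w = bundles.incidence()
    rng = np.random.default_rng(seed)
    kR, kT = len(regions), len(tracts)
    null = np.empty(B)
    for b in range(B):
        rmask = np.zeros(nR, dtype=bool)
        rmask[rng.choice(nR, size=kR, replace=False)] = True
        tmask = np.zeros(nT, dtype=bool)
        tmask[rng.choice(nT, size=kT, replace=False)] = True
        hit = rmask[ridx[:, 0]] & rmask[ridx[:, 1]] & (tinc @ tmask)
        null[b] = w[hit].sum()
    p = float((1 + (null >= observed).sum()) / (B + 1))
    return PatternTestResult(
        observed=observed,
        null_weights=null,
        p_value=p,
        n_regions=kR,
        n_tracts=kT,
        n_permutations=B,
        seed=seed,
    )
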
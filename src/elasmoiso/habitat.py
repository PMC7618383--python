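"""Distributional comparisons and habitat-use classification for tooth δ18Op.

Covers the nonparametric toolkit used on the measurement tables: the
Kruskal–Wallis rank test across stratigraphic units (TELMs) or guilds, the
Dunn post hoc pairwise test, z-score flagging of low outliers (brackish
excursions), grouped summary tables, and the envelope-overlap habitat-use
classifier: a taxon×TELM δ18Op distribution is read against the local
seasonal δ18Op* envelope and the co-occurring bivalve phosphate-equivalent
median and labelled local, warm/brackish-shifted, cold/deep-shifted or
bimodal/mixed.

Both rank tests offer an exact small-sample mode (``method="exact"``) that
enumerates the permutation distribution of the statistic; the default
asymptotic mode matches the conventional chi-square / normal reference
distributions used in the field.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import MonthlyEnvelope

__all__ = [
    "ToothMeasurement",
    "GroupComparison",
    "HabitatCall",
    "ClassifierThresholds",
    "kruskal_wallis",
    "dunn_posthoc",
    "flag_outliers",
    "summarize_by",
    "classify_habitat_use",
    "guild_compare",
    "measurements_frame",
]

GUILDS = ("pelagic", "benthic")
HABITAT_LABELS = (
    "local",
    "warm_or_brackish_shifted",
    "cold_or_deep_shifted",
    "bimodal_mixed",
    "insufficient_n",
)


@dataclass
class ToothMeasurement:
    """One calibrated tooth δ18Op measurement with its metadata."""

    specimen_id: str
    taxon: str
    telm: int
    guild: str
    d18Op: float
    analytical_sd: float = 0.3

    def __post_init__(self) -> None:
        if not (2 <= self.telm <= 7):
            raise ValueError("telm must be 2-7")
        if self.guild not in GUILDS:
            raise ValueError(f"guild must be one of {GUILDS}")
        if not (10.0 <= self.d18Op <= 30.0):
            raise ValueError(f"δ18Op {self.d18Op} outside the 10-30‰ sanity window")


def measurements_frame(measurements: Iterable[ToothMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen_id": m.specimen_id,
                "taxon": m.taxon,
                "telm": m.telm,
                "guild": m.guild,
                "d18Op": m.d18Op,
                "analytical_sd": m.analytical_sd,
            }
            for m in measurements
        ]
    )


@dataclass
class GroupComparison:
    """A Kruskal–Wallis result with optional Dunn pairwise table."""

    H: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None
    adjustment: str = "none"


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2):
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return arrs


def _h_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    n = pooled_ranks.size
    h = 0.0
    start = 0
    for sz in sizes:
        r = pooled_ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _tie_correction(values: np.ndarray) -> float:
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> tuple[float, int, float]:
    """Kruskal–Wallis H test with mid-rank ties and tie correction.

    Returns (H, df, p). ``method="asymptotic"`` uses the chi-square reference
    (df = k−1); ``method="exact"`` enumerates the permutation distribution of
    H (P(H_perm ≥ H_obs)) — only feasible for small pooled n.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    df = k - 1
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    if method == "asymptotic":
        h, p = stats.kruskal(*arrs)
        return float(h), df, float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    sizes = [g.size for g in arrs]
    ranks = stats.rankdata(pooled)
    tie = _tie_correction(pooled)
    h_obs = _h_statistic(ranks, sizes, tie)
    count = 0
    total = 0
    for perm_ranks in _group_assignments(ranks, sizes):
        h = _h_statistic(perm_ranks, sizes, tie)
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return float(h_obs), df, count / total


def _group_assignments(ranks: np.ndarray, sizes: Sequence[int]):
    """All distinct assignments of pooled ranks to groups of the given sizes."""
    n = ranks.size
    idx = np.arange(n)

    def rec(remaining: tuple, sizes_left):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        sz = sizes_left[0]
        for combo in itertools.combinations(remaining, sz):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    for assignment in rec(tuple(idx), list(sizes)):
        order = [i for grp in assignment for i in grp]
        yield ranks[np.array(order)]


def _adjust(p: np.ndarray, adjustment: str) -> np.ndarray:
    m = p.size
    if adjustment == "none":
        return p
    if adjustment == "bonferroni":
        return np.minimum(p * m, 1.0)
    if adjustment == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {adjustment!r}")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "none",
    labels: Sequence[str] | None = None,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Dunn's post hoc pairwise test on pooled mid-ranks with tie correction.

    Returns a tidy table (group_a, group_b, z, p, p_adjusted). ``method="exact"``
    replaces the two-sided normal p with the exact permutation p of |z|.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = np.sum(counts**3 - counts)
    rows = []
    degenerate = np.ptp(pooled) == 0
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        if degenerate or se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            if method == "asymptotic":
                p = 2.0 * stats.norm.sf(abs(z))
            elif method == "exact":
                p = _exact_pairwise_p(ranks, bounds, sizes, i, j, se, abs(z))
            else:
                raise ValueError(f"unknown method {method!r}")
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust(table["p"].to_numpy(), adjustment)
    table.attrs["adjustment"] = adjustment
    return table


def _exact_pairwise_p(ranks, bounds, sizes, i, j, se, abs_z) -> float:
    """Exact permutation p for one Dunn pair: |z| under relabelling of the two groups."""
    sub = np.concatenate(
        [ranks[bounds[i] : bounds[i + 1]], ranks[bounds[j] : bounds[j + 1]]]
    )
    ni = sizes[i]
    count = total = 0
    for combo in itertools.combinations(range(sub.size), ni):
        mask = np.zeros(sub.size, dtype=bool)
        mask[list(combo)] = True
        z = (sub[mask].mean() - sub[~mask].mean()) / se
        if abs(z) >= abs_z - 1e-12:
            count += 1
        total += 1
    return count / total


def flag_outliers(values: Sequence[float], threshold: float = -2.0) -> pd.DataFrame:
    """z-scores over a comparison pool; flag values with z below the threshold.

    The pool is whatever the caller passes (bulk, per-TELM or per-taxon).
    A zero-SD pool is degenerate: all z are NaN and flagged as such.
    """
    v = np.asarray(list(values), dtype=float)
    sd = np.std(v, ddof=1) if v.size > 1 else 0.0
    degenerate = sd == 0 or v.size < 2
    z = np.full(v.size, np.nan) if degenerate else (v - v.mean()) / sd
    return pd.DataFrame(
        {
            "value": v,
            "z": z,
            "outlier": np.zeros(v.size, dtype=bool) if degenerate else z < threshold,
            "degenerate": degenerate,
        }
    )


def summarize_by(df: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Grouped summary table (n, mean, sd, median, min, max) of δ18Op values.

    Mirrors the layout of per-TELM / per-guild summary tables; values are
    full precision (round for display only). Single-value groups report
    sd = 0 with ``sd_undefined`` flagged.
    """
    for key in keys:
        if key not in df.columns:
            raise ValueError(f"unknown grouping key {key!r}")
    rows = []
    for vals, g in df.groupby(list(keys), sort=True):
        if not isinstance(vals, tuple):
            vals = (vals,)
        x = g["d18Op"].to_numpy()
        rows.append(
            dict(zip(keys, vals))
            | {
                "n": x.size,
                "mean": float(x.mean()),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "sd_undefined": x.size < 2,
                "median": float(np.median(x)),
                "min": float(x.min()),
                "max": float(x.max()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClassifierThresholds:
    """Tunable thresholds of the envelope-overlap habitat classifier (‰)."""

    min_n: int = 4
    inside_fraction: float = 0.75
    bivalve_offset: float = 0.5
    envelope_margin: float = 0.5
    bivalve_shift: float = 1.0
    mode_separation: float = 1.0
    mode_min_height: float = 0.25  # modes below this fraction of the peak are noise


@dataclass
class HabitatCall:
    """A habitat-use label for one taxon×TELM distribution, with its evidence."""

    taxon: str
    telm: int
    label: str
    median_offset_envelope: float
    median_offset_bivalve: float
    fraction_inside: float
    mode_count: int
    n: int


def _count_modes(values: np.ndarray, thresholds: ClassifierThresholds) -> tuple[int, float]:
    """KDE mode count and the largest separation between retained modes."""
    if np.ptp(values) == 0:
        return 1, 0.0
    kde = stats.gaussian_kde(values)
    span = np.ptp(values)
    grid = np.linspace(values.min() - 0.5 * span, values.max() + 0.5 * span, 512)
    dens = kde(grid)
    peaks = [
        i
        for i in range(1, grid.size - 1)
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]
    ]
    if not peaks:
        return 1, 0.0
    top = dens[peaks].max()
    modes = [grid[i] for i in peaks if dens[i] >= thresholds.mode_min_height * top]
    sep = max(modes) - min(modes) if len(modes) > 1 else 0.0
    return len(modes), float(sep)


def classify_habitat_use(
    taxon_values: Sequence[float],
    site_envelope: MonthlyEnvelope,
    bivalve_equiv_median: float,
    regional_envelope: MonthlyEnvelope | None = None,
    thresholds: ClassifierThresholds | None = None,
    taxon: str = "",
    telm: int = 5,
) -> HabitatCall:
    """Classify a taxon×TELM δ18Op distribution against local references.

    Logic (deterministic given the evidence and thresholds): with fewer than
    ``min_n`` values the call is ``insufficient_n``. A clearly bimodal
    distribution (≥2 KDE modes separated beyond ``mode_separation``) is
    ``bimodal_mixed``. A median below the envelope minimum by more than
    ``envelope_margin`` or below the bivalve median by more than
    ``bivalve_shift`` is ``warm_or_brackish_shifted`` (lower δ18Op ⇒ warmer
    and/or fresher water); the symmetric high-side test gives
    ``cold_or_deep_shifted``. Otherwise the taxon reads as ``local`` —
    agreement with seasonal conditions at the site, with the fraction of
    values inside the envelope and the bivalve offset reported as evidence.
    """
    if site_envelope is None:
        raise ValueError("a site envelope is required")
    th = thresholds or ClassifierThresholds()
    v = np.asarray(list(taxon_values), dtype=float)
    lo, hi = site_envelope.range_of("d18Op_star")
    center = 0.5 * (lo + hi)
    n = v.size
    if n == 0:
        raise ValueError("no values to classify")
    med = float(np.median(v))
    inside = float(np.mean((v >= lo) & (v <= hi)))
    mode_count, mode_sep = _count_modes(v, th) if n >= th.min_n else (1, 0.0)
    evidence = dict(
        median_offset_envelope=med - center,
        median_offset_bivalve=med - bivalve_equiv_median,
        fraction_inside=inside,
        mode_count=mode_count,
        n=n,
    )
    if n < th.min_n:
        label = "insufficient_n"
    elif mode_count >= 2 and mode_sep > th.mode_separation:
        label = "bimodal_mixed"
    elif med < lo - th.envelope_margin or med < bivalve_equiv_median - th.bivalve_shift:
        label = "warm_or_brackish_shifted"
    elif med > hi + th.envelope_margin or med > bivalve_equiv_median + th.bivalve_shift:
        label = "cold_or_deep_shifted"
    else:
        label = "local"
    return HabitatCall(taxon=taxon, telm=telm, label=label, **evidence)


def guild_compare(df: pd.DataFrame, per_telm: bool = True) -> pd.DataFrame:
    """Pelagic-vs-benthic Kruskal–Wallis comparison, optionally per TELM.

    Mirrors the per-TELM summary-plus-test table layout. A TELM missing one
    guild yields a flagged row (no test computed) rather than an error.
    """
    rows = []
    telms = sorted(df["telm"].unique()) if per_telm else [None]
    for telm in telms:
        sub = df if telm is None else df[df["telm"] == telm]
        groups = {g: sub.loc[sub["guild"] == g, "d18Op"].to_numpy() for g in GUILDS}
        base = {"telm": telm if telm is not None else "all"}
        for g in GUILDS:
            x = groups[g]
            base[f"n_{g}"] = int(x.size)
            base[f"mean_{g}"] = float(x.mean()) if x.size else float("nan")
        if any(groups[g].size == 0 for g in GUILDS):
            rows.append(base | {"H": float("nan"), "p": float("nan"), "flagged": True})
            continue
        h, _, p = kruskal_wallis([groups["pelagic"], groups["benthic"]])
        rows.append(base | {"H": h, "p": p, "flagged": False})
    return pd.DataFrame(rows)
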
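"""Three-group permutation inference with Bonferroni correction.

The omnibus test permutes group labels and uses the between-group sum of
squares ``sum_g n_g (mean_g - grand_mean)^2`` (the one-way ANOVA
numerator) as the statistic; pairwise tests use the absolute difference
of group means.  p-values carry the +1 small-sample correction,
``p = (1 + #{perm >= obs}) / (1 + n_perm)``, so they are never zero.
Pairwise tests run only when the omnibus test rejects at the chosen
level, and their p-values are Bonferroni-corrected by the factor 3 (the
three pairwise comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from eegfc.errors import ConfigurationError, DataError

DEFAULT_N_PERM = 10_000


@dataclass
class GroupComparison:
    """Omnibus and (gated) pairwise permutation results for one parameter/band/region."""

    parameter: str
    band: str
    region: str
    omnibus_p: float
    pairwise_p: dict[str, float]  # Bonferroni-corrected; empty unless omnibus rejects
    group_means: dict[str, float]
    n_permutations: int
    seed: int
    alpha: float = 0.05


def _check_groups(values: np.ndarray, labels: np.ndarray, min_per_group: int = 2) -> list:
    groups = sorted(pd.unique(labels).tolist())
    for g in groups:
        if int(np.sum(labels == g)) < min_per_group:
            raise DataError(f"group {g!r} has fewer than {min_per_group} subjects")
    return groups


def _between_group_ss(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss = 0.0
    for g in range(n_groups):
        v = values[group_idx == g]
        ss += v.size * (v.mean() - grand) ** 2
    return ss


def permutation_omnibus(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Permutation p-value for any location difference among the groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise DataError("values and labels length mismatch")
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    groups = _check_groups(values, labels)
    gmap = {g: i for i, g in enumerate(groups)}
    gidx = np.array([gmap[l] for l in labels])
    n_groups = len(groups)
    obs = _between_group_ss(values, gidx, n_groups)
    rng = np.random.default_rng(seed)
    # permute labels in bulk; group sizes are invariant under permutation
    perms = rng.permuted(np.tile(gidx, (n_perm, 1)), axis=1)
    grand = values.mean()
    stats = np.zeros(n_perm)
    for g in range(n_groups):
        n_g = int(np.sum(gidx == g))
        means_g = ((perms == g) @ values) / n_g
        stats += n_g * (means_g - grand) ** 2
    count = int(np.sum(stats >= obs - 1e-12))
    return (1 + count) / (1 + n_perm)


def permutation_pairwise(
    values: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Raw two-group permutation p-value, statistic |difference of means|.

    With ``exhaustive=True`` all label splits are enumerated and the
    exact p-value ``#{splits with stat >= obs} / #splits`` is returned
    (only sensible for small samples).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = np.isin(labels, list(pair))
    v = values[mask]
    l = labels[mask]
    _check_groups(v, l)
    a = v[l == pair[0]]
    b = v[l == pair[1]]
    obs = abs(a.mean() - b.mean())
    n_a, n = a.size, v.size
    if exhaustive:
        idx_all = set(range(n))
        count = total = 0
        for comb in combinations(range(n), n_a):
            sel = np.fromiter(comb, dtype=int)
            rest = np.fromiter(idx_all - set(comb), dtype=int)
            stat = abs(v[sel].mean() - v[rest].mean())
            total += 1
            if stat >= obs - 1e-12:
                count += 1
        return count / total
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    pv = rng.permuted(np.tile(v, (n_perm, 1)), axis=1)
    total = v.sum()
    sum_a = pv[:, :n_a].sum(axis=1)
    stats = np.abs(sum_a / n_a - (total - sum_a) / (n - n_a))
    count = int(np.sum(stats >= obs - 1e-12))
    return (1 + count) / (1 + n_perm)


def bonferroni(raw_ps: dict[str, float] | list[float], m: int = 3) -> dict[str, float] | list[float]:
    """Multiply each p by the number of comparisons, cap at 1."""
    if isinstance(raw_ps, dict):
        return {k: min(1.0, m * p) for k, p in raw_ps.items()}
    return [min(1.0, m * p) for p in raw_ps]


def compare_all(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[GroupComparison]:
    """Omnibus + gated pairwise comparisons for every (parameter, band, region).

    ``table`` is tidy with columns subject, group, band, parameter,
    region, value and must contain exactly three groups.  Pairwise
    p-values are Bonferroni-corrected (factor 3) and only computed when
    the omnibus test rejects at ``alpha``.
    """
    required = {"group", "band", "parameter", "region", "value"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"metrics table missing columns: {sorted(missing)}")
    groups = sorted(table["group"].unique().tolist())
    if len(groups) != 3:
        raise DataError(f"expected exactly 3 groups, found {groups}")
    pairs = list(combinations(groups, 2))
    results = []
    cells = sorted(table.groupby(["parameter", "band", "region"]).groups.keys())
    ss = np.random.SeedSequence(seed)
    cell_seeds = {cell: int(s.generate_state(1)[0] % (2**31)) for cell, s in
                  zip(cells, ss.spawn(len(cells)))}
    for parameter, band, region in cells:
        sub = table[
            (table["parameter"] == parameter)
            & (table["band"] == band)
            & (table["region"] == region)
        ]
        values = sub["value"].to_numpy(dtype=float)
        labels = sub["group"].to_numpy()
        cell_seed = cell_seeds[(parameter, band, region)]
        omni = permutation_omnibus(values, labels, n_perm=n_perm, seed=cell_seed)
        pairwise: dict[str, float] = {}
        if omni < alpha:
            raw = {
                f"{a}_vs_{b}": permutation_pairwise(
                    values, labels, (a, b), n_perm=n_perm, seed=cell_seed + k + 1
                )
                for k, (a, b) in enumerate(pairs)
            }
            pairwise = bonferroni(raw, m=len(pairs))
        results.append(
            GroupComparison(
                parameter=parameter,
                band=band,
                region=region,
                omnibus_p=omni,
                pairwise_p=pairwise,
                group_means={g: float(values[labels == g].mean()) for g in groups},
                n_permutations=n_perm,
                seed=cell_seed,
                alpha=alpha,
            )
        )
    return results


def comparisons_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison results to a tidy DataFrame for export."""
    records = []
    for r in results:
        rec = {
            "parameter": r.parameter,
            "band": r.band,
            "region": r.region,
            "omnibus_p": r.omnibus_p,
            "n_permutations": r.n_permutations,
        }
        for pair, p in r.pairwise_p.items():
            rec[f"p_{pair}"] = p
        for g, m in r.group_means.items():
            rec[f"mean_{g}"] = m
        records.append(rec)
    return pd.DataFrame.from_records(records)
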
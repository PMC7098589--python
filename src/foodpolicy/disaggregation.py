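"""Expansion of an aggregated price-elasticity matrix to sub-food resolution.

Own-PEs strengthen as a food group is split: with a strengthening scalar *s*
(central 0.025) and *k* sub-foods, each sub-food own-PE gains magnitude
``k*s`` relative to the aggregate own-PE (multiplicatively by default).  The
gained magnitude is returned as positive within-group cross-PEs (split
siblings are substitutes) allocated in proportion to expenditure shares:
the cross-PE of sub-food j onto sub-food i is ``share_j/(1-share_i) * inc``.

This construction makes every within-group row sum equal the aggregate
own-PE, so a uniform price change across the whole group reproduces the
aggregate response food-by-food.  Between-group blocks are allocated so the
same row-sum identity holds (``epsilon_ij = cross * share_j``, the
expenditure-proportional rule); a ``uniform`` mode replicating the aggregate
cross-PE to every sub-pair is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demand import PEMatrix

__all__ = [
    "DisaggregationScheme",
    "disaggregate_group",
    "disaggregate_cross_block",
    "disaggregate_matrix",
    "check_adding_up",
    "reaggregation_residuals",
]

OWN_MODES = ("multiplicative", "additive")
CROSS_MODES = ("proportional", "uniform")


@dataclass
class DisaggregationScheme:
    """Mapping from aggregate food groups to sub-foods with within-group
    expenditure shares, plus the own-PE strengthening scalar.

    ``groups`` maps group_id -> list of ``(sub_food_id, share)``; shares in
    each group must sum to 1.  ``s`` is the strengthening per sub-food
    (fraction, central 0.025) with standard deviation ``sd_s`` (0.0125) used
    by the uncertainty machinery; sampled values are truncated at 0.
    """

    groups: dict[str, list[tuple[str, float]]]
    s: float = 0.025
    sd_s: float = 0.0125

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("strengthening scalar must be >= 0")
        if self.sd_s < 0:
            raise ValueError("sd_s must be >= 0")
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if not members:
                raise ValueError(f"group {gid!r} has no sub-foods")
            shares = np.array([sh for _, sh in members], dtype=float)
            if np.any(shares < 0):
                raise ValueError(f"negative share in group {gid!r}")
            if abs(shares.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"shares in group {gid!r} sum to {shares.sum()}, not 1"
                )
            for sid, _ in members:
                if sid in seen:
                    raise ValueError(f"duplicate sub-food id {sid!r}")
                seen.add(sid)

    @property
    def sub_food_ids(self) -> list[str]:
        return [sid for members in self.groups.values() for sid, _ in members]

    def shares(self, group_id: str) -> np.ndarray:
        return np.array([sh for _, sh in self.groups[group_id]], dtype=float)


def disaggregate_group(
    own_pe_agg: float,
    shares: np.ndarray,
    s: float = 0.025,
    mode: str = "multiplicative",
) -> np.ndarray:
    """Diagonal block for one group split into ``k = len(shares)`` sub-foods.

    Every sub-food own-PE is the aggregate own-PE strengthened by ``k*s``
    (``|own_agg|*(1+k*s)`` multiplicatively, ``|own_agg|+k*s`` additively);
    the within-group cross-PE of sub-food j onto sub-food i is
    ``share_j/(1-share_i) * inc`` where ``inc`` is the magnitude gained.
    Rows of the block sum to ``own_pe_agg`` exactly.
    """
    shares = np.asarray(shares, dtype=float)
    k = shares.size
    if k == 0:
        raise ValueError("empty group")
    if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("shares must be non-negative and sum to 1")
    if own_pe_agg > 0:
        raise ValueError("aggregate own-PE must be <= 0")
    if mode not in OWN_MODES:
        raise ValueError(f"mode must be one of {OWN_MODES}")
    if k == 1:
        return np.array([[own_pe_agg]])
    mag = abs(own_pe_agg)
    if mode == "multiplicative":
        inc = mag * k * s
    else:
        inc = k * s
    block = np.empty((k, k))
    for i in range(k):
        denom = 1.0 - shares[i]
        if denom <= 0:
            raise ValueError("a sub-food holds the entire group share")
        for j in range(k):
            if i == j:
                block[i, j] = -(mag + inc)
            else:
                block[i, j] = shares[j] / denom * inc
    return block


def disaggregate_cross_block(
    cross_pe_agg: float,
    row_shares: np.ndarray,
    col_shares: np.ndarray,
    mode: str = "proportional",
) -> np.ndarray:
    """Between-group block: effect of price changes in the column group on
    quantities of the row group's sub-foods.

    ``proportional`` (default) allocates the aggregate cross-PE over column
    sub-foods by expenditure share (``epsilon_ij = cross * col_share_j``), so
    each row sums to the aggregate cross-PE; ``uniform`` replicates the
    aggregate value to every sub-pair.
    """
    row_shares = np.asarray(row_shares, dtype=float)
    col_shares = np.asarray(col_shares, dtype=float)
    if row_shares.size == 0 or col_shares.size == 0:
        raise ValueError("empty group")
    if mode not in CROSS_MODES:
        raise ValueError(f"mode must be one of {CROSS_MODES}")
    if mode == "uniform":
        return np.full((row_shares.size, col_shares.size), cross_pe_agg)
    return np.tile(cross_pe_agg * col_shares, (row_shares.size, 1))


def disaggregate_matrix(
    pe_agg: PEMatrix,
    scheme: DisaggregationScheme,
    group_order: list[str] | None = None,
    s: float | None = None,
    own_mode: str = "multiplicative",
    cross_mode: str = "proportional",
) -> PEMatrix:
    """Assemble the fine matrix from diagonal and between-group blocks.

    ``group_order`` gives the aggregate matrix's row/column labels (defaults
    to ``pe_agg.food_id``, else the scheme's insertion order).  Standard
    deviations, when present, are expanded with the same allocation rules.
    """
    if group_order is None:
        group_order = pe_agg.food_id or list(scheme.groups)
    if len(group_order) != pe_agg.n:
        raise ValueError("group_order length must match aggregate matrix")
    missing = [g for g in group_order if g not in scheme.groups]
    if missing:
        raise KeyError(f"scheme missing groups {missing}")
    if s is None:
        s = scheme.s

    shares = {g: scheme.shares(g) for g in group_order}
    sizes = [shares[g].size for g in group_order]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_fine = int(offsets[-1])
    fine = np.zeros((n_fine, n_fine))
    fine_sd = np.zeros((n_fine, n_fine)) if pe_agg.sd is not None else None

    for a, ga in enumerate(group_order):
        ra = slice(offsets[a], offsets[a + 1])
        for b, gb in enumerate(group_order):
            cb = slice(offsets[b], offsets[b + 1])
            if a == b:
                fine[ra, cb] = disaggregate_group(
                    pe_agg.epsilon[a, a], shares[ga], s, mode=own_mode
                )
                if fine_sd is not None:
                    # expand the own-PE sd with the same relative structure
                    ratio = np.divide(
                        fine[ra, cb], pe_agg.epsilon[a, a],
                        out=np.ones_like(fine[ra, cb]),
                        where=pe_agg.epsilon[a, a] != 0,
                    )
                    fine_sd[ra, cb] = np.abs(ratio) * pe_agg.sd[a, a]
            else:
                fine[ra, cb] = disaggregate_cross_block(
                    pe_agg.epsilon[a, b], shares[ga], shares[gb],
                    mode=cross_mode,
                )
                if fine_sd is not None:
                    if cross_mode == "uniform":
                        fine_sd[ra, cb] = pe_agg.sd[a, b]
                    else:
                        fine_sd[ra, cb] = np.tile(
                            pe_agg.sd[a, b] * shares[gb], (shares[ga].size, 1)
                        )

    sub_ids = [sid for g in group_order for sid, _ in scheme.groups[g]]
    return PEMatrix(epsilon=fine, sd=fine_sd, food_id=sub_ids)


def check_adding_up(
    pe: PEMatrix, w: np.ndarray, constant: np.ndarray | None = None
) -> np.ndarray:
    """Cournot-aggregation residuals per price column.

    Returns ``sum_i w_i * epsilon_ij - c_j`` for each column j, where the
    adding-up constant ``c_j`` defaults to ``-w_j`` (a full-budget demand
    system).  Diagnostic only: never raises.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (pe.n,):
        raise ValueError("share vector length must match matrix")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    c = -w if constant is None else np.asarray(constant, dtype=float)
    return w @ pe.epsilon - c


def reaggregation_residuals(
    fine: PEMatrix,
    pe_agg: PEMatrix,
    scheme: DisaggregationScheme,
    group_order: list[str] | None = None,
) -> np.ndarray:
    """Row-sum consistency of a fine matrix with its aggregate parent.

    For each fine food i and each price group B, the response of i to a
    uniform 1% price rise across all of B is ``sum_{j in B} epsilon_ij``;
    under the default allocation rules this equals the aggregate entry
    ``epsilon_agg[group(i), B]`` exactly.  Returns the (n_fine, n_groups)
    matrix of differences.
    """
    if group_order is None:
        group_order = pe_agg.food_id or list(scheme.groups)
    sizes = [scheme.shares(g).size for g in group_order]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_fine = int(offsets[-1])
    if fine.n != n_fine:
        raise ValueError("fine matrix dimension inconsistent with scheme")
    res = np.empty((n_fine, len(group_order)))
    row_group = np.repeat(np.arange(len(group_order)), sizes)
    for b in range(len(group_order)):
        cb = slice(offsets[b], offsets[b + 1])
        block_sum = fine.epsilon[:, cb].sum(axis=1)
        res[:, b] = block_sum - pe_agg.epsilon[row_group, b]
    return res
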
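"""Grey relational analysis (GRA) feature ranking and redundancy-aware
feature selection.

GRA, from Deng's grey system theory, scores how closely the shape of a
comparison sequence follows a reference sequence.  With normalized
sequences, per-point absolute differences Δ_i(k) = |x0(k) − xi(k)|,
and two-level extrema Δmin = min_i min_k Δ, Δmax = max_i max_k Δ, the
grey relational coefficient is

    γ_i(k) = (Δmin + ρ·Δmax) / (Δ_i(k) + ρ·Δmax)

with identification coefficient ρ (default 0.5), and the grey
relational degree (GRD) of sequence i is the mean of γ_i(k) over k.
A feature whose GRD with the target is high tracks the target closely;
a pair of features with near-±1 Pearson correlation is redundant.

Selection is greedy by descending GRD: keep a feature iff its GRD
exceeds a floor and its |R| with every feature already kept stays
below a redundancy ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GraConfig:
    rho: float = 0.5
    normalization: str = "minmax"  # or "zscore"
    #: two-level extrema over all comparison sequences (Deng's standard
    #: form); per-sequence extrema available for sensitivity analysis
    global_extrema: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if self.normalization not in ("minmax", "zscore"):
            raise ValueError("normalization must be 'minmax' or 'zscore'")


def normalize_sequences(table: pd.DataFrame, method: str = "minmax") -> pd.DataFrame:
    """Column-wise normalization applied before GRA.

    minmax maps each column onto [0, 1]; zscore centres and scales to
    unit variance.  A constant column cannot be normalized and raises,
    naming the column.
    """
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(float)
        if method == "minmax":
            lo, hi = x.min(), x.max()
            if hi == lo:
                raise ValueError(f"column {col!r} is constant; cannot min-max normalize")
            out[col] = (x - lo) / (hi - lo)
        elif method == "zscore":
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"column {col!r} is constant; cannot z-score normalize")
            out[col] = (x - x.mean()) / sd
        else:
            raise ValueError(f"unknown normalization {method!r}")
    return pd.DataFrame(out, index=table.index)


@dataclass(frozen=True)
class GraResult:
    """GRD of each comparison feature against the reference variable."""

    reference: str
    grd: pd.Series  # indexed by feature name
    rank: pd.Series  # 1 = highest GRD; ties broken by name ascending

    def ordered_features(self) -> list[str]:
        return list(self.rank.sort_values().index)


def grd(
    reference: np.ndarray | pd.Series,
    comparisons: pd.DataFrame,
    config: GraConfig = GraConfig(),
    reference_name: str = "reference",
) -> GraResult:
    """Grey relational degree of each comparison sequence.

    Sequences must be pre-normalized and of equal length n >= 2.  If
    every Δ is identically zero (all sequences equal the reference)
    every GRD is 1 by convention.
    """
    x0 = np.asarray(reference, float)
    X = comparisons.to_numpy(float)
    if X.shape[0] != x0.shape[0]:
        raise ValueError(
            f"length mismatch: reference n={x0.shape[0]}, comparisons n={X.shape[0]}"
        )
    if x0.shape[0] < 2:
        raise ValueError("sequences must have length >= 2")

    delta = np.abs(X - x0[:, None])  # (n, m)
    if config.global_extrema:
        dmin, dmax = delta.min(), delta.max()
        if dmax == 0:
            g = np.ones_like(delta)
        else:
            g = (dmin + config.rho * dmax) / (delta + config.rho * dmax)
    else:
        dmin = delta.min(axis=0, keepdims=True)
        dmax = delta.max(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            g = (dmin + config.rho * dmax) / (delta + config.rho * dmax)
        g = np.where(dmax == 0, 1.0, g)

    grd_vals = pd.Series(g.mean(axis=0), index=comparisons.columns, name="GRD")
    order = sorted(grd_vals.index, key=lambda c: (-grd_vals[c], c))
    rank = pd.Series({c: i + 1 for i, c in enumerate(order)}, name="rank")
    return GraResult(reference=reference_name, grd=grd_vals, rank=rank[grd_vals.index])


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between feature columns."""
    if len(table) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sds = table.std(ddof=1)
    constant = list(sds.index[sds == 0])
    if constant:
        raise ValueError(f"constant column(s) {constant}: correlation undefined")
    return table.corr(method="pearson")


@dataclass(frozen=True)
class SelectionRules:
    """The two selection rules: high relevance, low redundancy."""

    grd_floor: float = 0.65
    redundancy_ceiling: float = 0.9
    max_selected: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.grd_floor <= 1:
            raise ValueError("grd_floor must lie in [0, 1]")
        if not 0 <= self.redundancy_ceiling <= 1:
            raise ValueError("redundancy_ceiling must lie in [0, 1]")

    @classmethod
    def strict(cls) -> "SelectionRules":
        """Default: reject any pair with |R| >= 0.9."""
        return cls()

    @classmethod
    def relaxed(cls) -> "SelectionRules":
        """Redundancy ceiling 0.975: admits one near-collinear pigment
        index pair that the strict rule would prune, trading a little
        redundancy for an extra visible-band feature."""
        return cls(redundancy_ceiling=0.975)


PRESETS = {"strict": SelectionRules.strict, "relaxed": SelectionRules.relaxed}


def select_features(
    gra: GraResult,
    corr: pd.DataFrame,
    rules: SelectionRules = SelectionRules(),
) -> list[str]:
    """Greedy selection by descending GRD under the two rules.

    A candidate is accepted iff GRD > grd_floor and |R| with every
    already-accepted feature < redundancy_ceiling.  Ties in GRD break
    by feature name ascending, so the output is deterministic.
    """
    feats = set(gra.grd.index)
    if not feats <= set(corr.index) or not feats <= set(corr.columns):
        raise ValueError("GRA result and correlation matrix cover different features")
    selected: list[str] = []
    for name in gra.ordered_features():
        if gra.grd[name] <= rules.grd_floor:
            continue
        if any(abs(corr.loc[name, s]) >= rules.redundancy_ceiling for s in selected):
            continue
        selected.append(name)
        if rules.max_selected is not None and len(selected) >= rules.max_selected:
            break
    return selected


def rank_and_select(
    table: pd.DataFrame,
    feature_cols: list[str],
    target_col: str,
    gra_config: GraConfig = GraConfig(),
    rules: SelectionRules = SelectionRules(),
) -> tuple[GraResult, pd.DataFrame, list[str]]:
    """Normalize, run GRA against the target, correlate features, select.

    Convenience wrapper chaining the full selection stage; returns the
    GRA result, the feature correlation matrix (computed on the raw,
    unnormalized features), and the ordered selection.
    """
    norm = normalize_sequences(table[feature_cols + [target_col]], gra_config.normalization)
    gra = grd(
        norm[target_col], norm[feature_cols], gra_config, reference_name=target_col
    )
    corr = correlation_matrix(table[feature_cols])
    return gra, corr, select_features(gra, corr, rules)
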
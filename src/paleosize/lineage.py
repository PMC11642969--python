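"""Ancestor–descendant lineage comparisons for surviving species.

Fossil and modern populations of a surviving lineage (or of an anagenetic
ancestor–descendant pair) are compared with two-sample t-tests — pooled and
Welch variants reported side by side — plus a permutation t-test, with
Bonferroni correction across the battery of lineages.  Unlike the
clade-level turnover analysis, lineage tests run on raw specimen lengths in
mm by default (population means are reported in mm); log-scale testing is a
switch.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .measurements import TimeBin, records_to_frame

__all__ = [
    "TTestVariant",
    "LineagePair",
    "TestOutcome",
    "two_sample_t",
    "permutation_t",
    "bonferroni_alpha",
    "run_lineage_battery",
    "extract_lineage_pairs",
]

#: exhaustive enumeration is used when the number of distinct group
#: assignments C(n1+n2, n1) does not exceed this
EXHAUSTIVE_LIMIT = 200_000


class TTestVariant(str, enum.Enum):
    POOLED = "pooled"
    WELCH = "welch"


@dataclass(frozen=True)
class LineagePair:
    """A fossil population and its modern counterpart.

    modern_species may differ from fossil_species for anagenetic pairs
    (e.g. *Torcula perattenuata* -> *T. exoleta*).
    """

    lineage_name: str
    fossil_species: str
    modern_species: str
    fossil_lengths: np.ndarray
    modern_lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fossil_lengths", np.asarray(self.fossil_lengths, dtype=float)
        )
        object.__setattr__(
            self, "modern_lengths", np.asarray(self.modern_lengths, dtype=float)
        )
        if self.fossil_lengths.size == 0 or self.modern_lengths.size == 0:
            raise ValueError(
                f"lineage {self.lineage_name!r}: both populations must be non-empty"
            )


@dataclass(frozen=True)
class TestOutcome:
    lineage_name: str
    n_fossil: int
    n_modern: int
    mean_fossil_mm: float
    mean_modern_mm: float
    t_pooled: float
    p_pooled: float
    df_pooled: float
    t_welch: float
    p_welch: float
    df_welch: float
    t_perm: float
    p_perm: float
    alpha: float
    m: int
    alpha_corrected: float
    significant_raw: bool
    significant_bonferroni: bool


def _validate_t_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t requires at least 2 values per sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("t statistic undefined: both samples have zero variance")


def two_sample_t(
    x, y, variant: TTestVariant | str = TTestVariant.POOLED
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, p, df).

    POOLED uses the classical equal-variance statistic; WELCH uses the
    unequal-variance statistic with Welch–Satterthwaite df.  t is positive
    when mean(x) > mean(y).
    """
    variant = TTestVariant(variant)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_t_inputs(x, y)
    res = stats.ttest_ind(x, y, equal_var=(variant is TTestVariant.POOLED))
    return float(res.statistic), float(res.pvalue), float(res.df)


def _pooled_t_matrix(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled t and pooled variance for labelings stacked as rows."""
    n1, n2 = xs.shape[1], ys.shape[1]
    m1, m2 = xs.mean(axis=1), ys.mean(axis=1)
    ss1 = ((xs - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((ys - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    if df <= 0:
        return np.full(len(xs), np.nan), np.zeros(len(xs))
    s2 = (ss1 + ss2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return t, s2


def permutation_t(
    x,
    y,
    n_perm: int = 9_999,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool | None = None,
) -> tuple[float, float]:
    """Permutation two-sample t-test; returns (t_obs, p).

    The statistic is the pooled two-sample t on each relabeling; if the
    pooled variance degenerates to zero under any evaluated labeling (or the
    t is undefined, e.g. singleton groups), the absolute mean difference is
    used as the statistic for every labeling instead.  ``exhaustive=None``
    auto-selects full enumeration of all C(n1+n2, n1) distinct assignments
    when feasible; otherwise ``n_perm`` Monte-Carlo relabelings are drawn and
    the observed labeling is counted among them, so p lies in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    n = n1 + n2
    if exhaustive is None:
        exhaustive = comb(n, n1) <= EXHAUSTIVE_LIMIT

    if exhaustive:
        labelings = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
            dtype=np.intp,
        ).reshape(-1, n1)
        mask = np.zeros((len(labelings), n), dtype=bool)
        np.put_along_axis(mask, labelings, True, axis=1)
        xs = combined[labelings]
        ys = np.broadcast_to(combined, mask.shape)[~mask].reshape(len(labelings), n2)
        obs_x, obs_y = x[None, :], y[None, :]
    else:
        rng = np.random.default_rng(rng)
        perms = rng.permuted(
            np.broadcast_to(combined, (int(n_perm), n)).copy(), axis=1
        )
        xs, ys = perms[:, :n1], perms[:, n1:]
        obs_x, obs_y = x[None, :], y[None, :]

    t_all, s2_all = _pooled_t_matrix(xs, ys)
    t_obs_arr, s2_obs = _pooled_t_matrix(obs_x, obs_y)
    degenerate = (
        np.isnan(t_all).any()
        or np.isnan(t_obs_arr).any()
        or (s2_all == 0).any()
        or (s2_obs == 0).any()
    )
    if degenerate:
        stat_all = np.abs(xs.mean(axis=1) - ys.mean(axis=1))
        stat_obs = abs(float(x.mean() - y.mean()))
        t_obs = float(x.mean() - y.mean())
    else:
        stat_all = np.abs(t_all)
        stat_obs = abs(float(t_obs_arr[0]))
        t_obs = float(t_obs_arr[0])

    # tolerance so the observed labeling always counts as "at least as extreme"
    tol = 1e-12 * max(1.0, stat_obs)
    extreme = int(np.count_nonzero(stat_all >= stat_obs - tol))
    if exhaustive:
        p = extreme / len(stat_all)
    else:
        p = (1 + extreme) / (len(stat_all) + 1)
    return t_obs, float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def run_lineage_battery(
    pairs: list[LineagePair],
    alpha: float = 0.05,
    m: int | None = None,
    n_perm: int = 9_999,
    seed: int = 0,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Run the full test battery on every lineage pair.

    One row per pair, in input order.  ``m`` defaults to the number of pairs
    tested.  Significance flags are based on the pooled-t p-value; the Welch
    and permutation variants are reported alongside.  ``log_scale`` tests
    natural-log lengths instead of mm (means are always reported in mm).
    """
    m = len(pairs) if m is None else m
    if pairs and m < 1:
        raise ValueError("m must be >= 1")
    corrected = bonferroni_alpha(alpha, m) if pairs else np.nan
    ss = np.random.SeedSequence(seed)
    rows = []
    for pair, child in zip(pairs, ss.spawn(max(len(pairs), 1))):
        fx, mx = pair.fossil_lengths, pair.modern_lengths
        tx, ty = (np.log(fx), np.log(mx)) if log_scale else (fx, mx)
        try:
            t_pooled, p_pooled, df_pooled = two_sample_t(tx, ty, TTestVariant.POOLED)
            t_welch, p_welch, df_welch = two_sample_t(tx, ty, TTestVariant.WELCH)
        except ValueError as err:
            raise ValueError(f"lineage {pair.lineage_name!r}: {err}") from err
        t_perm, p_perm = permutation_t(
            tx, ty, n_perm=n_perm, rng=np.random.default_rng(child)
        )
        rows.append(
            TestOutcome(
                lineage_name=pair.lineage_name,
                n_fossil=fx.size,
                n_modern=mx.size,
                mean_fossil_mm=float(fx.mean()),
                mean_modern_mm=float(mx.mean()),
                t_pooled=t_pooled,
                p_pooled=p_pooled,
                df_pooled=df_pooled,
                t_welch=t_welch,
                p_welch=p_welch,
                df_welch=df_welch,
                t_perm=t_perm,
                p_perm=p_perm,
                alpha=alpha,
                m=m,
                alpha_corrected=corrected,
                significant_raw=bool(p_pooled < alpha),
                significant_bonferroni=bool(p_pooled < corrected),
            ).__dict__
        )
    return pd.DataFrame(rows, columns=list(TestOutcome.__dataclass_fields__))


def extract_lineage_pairs(
    records,
    definitions: list[dict],
    include_figures: bool = True,
) -> list[LineagePair]:
    """Build LineagePair objects from a measurement table.

    Each definition is a mapping with keys ``name``, ``fossil_species``,
    ``modern_species``; fossil lengths come from the pre-extinction bin of
    fossil_species and modern lengths from the modern bin of modern_species.
    """
    df = records_to_frame(records)
    if not include_figures:
        df = df.loc[~df["from_figure"]]
    pairs = []
    for d in definitions:
        fossil = df.loc[
            (df["species"] == d["fossil_species"])
            & (df["time_bin"] == TimeBin.PRE_EXTINCTION.value),
            "length_mm",
        ].to_numpy()
        modern = df.loc[
            (df["species"] == d["modern_species"])
            & (df["time_bin"] == TimeBin.MODERN.value),
            "length_mm",
        ].to_numpy()
        if fossil.size == 0 or modern.size == 0:
            raise ValueError(
                f"lineage {d['name']!r}: no specimens found for one of the bins"
            )
        pairs.append(
            LineagePair(
                lineage_name=d["name"],
                fossil_species=d["fossil_species"],
                modern_species=d["modern_species"],
                fossil_lengths=fossil,
                modern_lengths=modern,
            )
        )
    return pairs
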
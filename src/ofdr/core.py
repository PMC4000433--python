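"""Two-step hierarchical hypothesis-set testing with directional decisions.

A *hypothesis set* bundles the hypotheses attached to one feature (typically a
gene): a screening hypothesis — the conjunction of the set's individual null
hypotheses — plus the ``n(i)`` individual two-sided nulls themselves.  The
two-step procedure implemented here

1. forms a screening p-value ``p0(i)`` per set, applies the Benjamini–Hochberg
   (BH) step-up at level ``alpha`` to the ``m`` screening p-values, and
2. inside each of the ``R`` rejected sets, tests the individual hypotheses with
   a family-wise error rate (FWER) controlling procedure — Bonferroni, Holm
   step-down, or Hochberg step-up — at level ``R * alpha / m``, declaring the
   direction of each rejected hypothesis from the sign of its test statistic.

This controls the overall false discovery rate (OFDR) and, because the three
FWER procedures also control directional errors for independent two-sided
statistics, the mixed-directional FDR (mdFDR), at level ``alpha`` under
independence across sets.  A one-step comparator (`run_simple_bh`) that pools
all individual p-values into a single BH pass is provided; it controls the FDR
of the individual hypotheses but not the set-wise mdFDR.

The variant procedures differ only in the screening p-value and second stage:

=============  ==========================================  ==============
method         screening p-value                           second stage
=============  ==========================================  ==============
``bonferroni`` ``q * p_(1)``                               Bonferroni
``holm``       ``q * p_(1)``                               Holm
``hochberg``   ``min_j (q + 1 - j) * p_(j)``               Hochberg
=============  ==========================================  ==============

Because ``bonferroni`` and ``holm`` share the screening p-value they always
reject identical sets; they may differ in which individual hypotheses they
reject within those sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PValueSetCollection",
    "ScreeningResult",
    "DecisionReport",
    "SecondStageRule",
    "screening_pvalue_bonferroni",
    "screening_pvalue_hochberg",
    "bh_step_up",
    "second_stage",
    "second_stage_rule",
    "run_two_step",
    "run_simple_bh",
    "TWO_STEP_METHODS",
    "ALL_METHODS",
]

TWO_STEP_METHODS = ("bonferroni", "holm", "hochberg")
ALL_METHODS = TWO_STEP_METHODS + ("simple_bh",)


def _validate_pvector(p: np.ndarray, what: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError(f"{what} must be a non-empty 1-d vector, got shape {p.shape}")
    if not np.all((p >= 0.0) & (p <= 1.0)):
        raise ValueError(f"{what} values must lie in [0, 1]")
    return p


def _validate_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha


@dataclass
class PValueSetCollection:
    """Ragged collection of hypothesis sets.

    Parameters
    ----------
    p
        Sequence of 1-d arrays; ``p[i]`` holds the ``n(i)`` individual
        p-values of set ``i``.  A 2-d array is accepted for the common case
        of a constant set size.
    sign
        Matching structure of values in {-1, 0, +1}: the sign of each
        underlying test statistic.  Defaults to all zero (no directional
        information).
    labels
        Opaque per-set identifiers (e.g. gene names).  Defaults to
        ``0 .. m-1``.
    """

    p: list[np.ndarray]
    sign: list[np.ndarray]
    labels: list

    def __init__(self, p, sign=None, labels=None):
        self._P = self._S = None  # cached rectangular form, when one exists
        if isinstance(p, np.ndarray) and p.ndim == 2:
            # rectangular fast path: validate and store as one matrix
            P = np.asarray(p, dtype=float)
            if P.shape[0] == 0 or P.shape[1] == 0:
                raise ValueError("collection must contain at least one non-empty set")
            if not np.all((P >= 0.0) & (P <= 1.0)):
                raise ValueError("p values must lie in [0, 1]")
            m = P.shape[0]
            if sign is None:
                S = np.zeros(P.shape, dtype=int)
            else:
                S = np.asarray(sign)
                if S.shape != P.shape:
                    raise ValueError(f"sign shape {S.shape} != p shape {P.shape}")
                if not np.all(np.isin(S, (-1, 0, 1))):
                    raise ValueError("sign must take values in {-1, 0, +1}")
                S = np.sign(S).astype(int)
            self._P, self._S = P, S
            self.p = list(P)
            self.sign = list(S)
        else:
            self.p = [
                _validate_pvector(np.asarray(v, dtype=float), f"p[{i}]")
                for i, v in enumerate(p)
            ]
            m = len(self.p)
            if m == 0:
                raise ValueError("collection must contain at least one hypothesis set")
            if sign is None:
                self.sign = [np.zeros(v.size, dtype=int) for v in self.p]
            else:
                self.sign = [np.asarray(s) for s in sign]
                if len(self.sign) != m:
                    raise ValueError("sign must have one vector per set")
                for i, (v, s) in enumerate(zip(self.p, self.sign)):
                    if s.shape != v.shape:
                        raise ValueError(f"sign[{i}] length {s.size} != p[{i}] length {v.size}")
                    if not np.all(np.isin(s, (-1, 0, 1))):
                        raise ValueError(f"sign[{i}] must take values in {{-1, 0, +1}}")
                self.sign = [np.sign(s).astype(int) for s in self.sign]
        self.labels = list(labels) if labels is not None else list(range(m))
        if len(self.labels) != m:
            raise ValueError("labels must have one entry per set")

    @property
    def n_sets(self) -> int:
        return len(self.p)

    @property
    def sizes(self) -> np.ndarray:
        """n(i), the number of individual hypotheses per set."""
        return np.array([v.size for v in self.p])

    @property
    def is_uniform(self) -> bool:
        if self._P is not None:
            return True
        sizes = self.sizes
        return bool(np.all(sizes == sizes[0]))

    def as_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, q) p-value and sign matrices; requires a constant set size."""
        if self._P is None:
            if not self.is_uniform:
                raise ValueError("set sizes vary; no rectangular representation exists")
            self._P, self._S = np.vstack(self.p), np.vstack(self.sign)
        return self._P, self._S

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        set_col: str = "set_id",
        p_col: str = "p_value",
        sign_col: str = "statistic_sign",
    ) -> "PValueSetCollection":
        """Build a collection from a long-format table (one row per hypothesis)."""
        missing = {set_col, p_col} - set(frame.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        p, sign, labels = [], [], []
        for label, grp in frame.groupby(set_col, sort=False):
            labels.append(label)
            p.append(grp[p_col].to_numpy(dtype=float))
            if sign_col in frame.columns:
                sign.append(grp[sign_col].to_numpy())
            else:
                sign.append(np.zeros(len(grp), dtype=int))
        return cls(p, sign, labels)


@dataclass
class ScreeningResult:
    """Outcome of the first (screening) stage."""

    p0: np.ndarray          # m screening p-values in [0, 1]
    rejected: np.ndarray    # boolean, length m
    R: int                  # number of rejected sets
    alpha: float

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        assert int(self.rejected.sum()) == self.R


@dataclass
class SecondStageRule:
    """The within-set step rule of Holm/Hochberg at level Rα/m.

    ``r`` is the largest index j (1-based) satisfying the step condition, or 0
    when no index does, in which case nothing in the set is rejected.
    """

    within_set_level: float
    n: int
    r: int

    def __post_init__(self):
        if not 0 <= self.r <= self.n:
            raise ValueError("rule index out of range")


@dataclass
class DecisionReport:
    """Full decisions of a procedure on one collection.

    The per-hypothesis structures mirror the (possibly ragged) shape of the
    input collection.  ``direction[i][j]`` is the declared sign of the effect
    for a rejected hypothesis and 0 otherwise.
    """

    screening: ScreeningResult
    individual_rejected: list[np.ndarray]
    direction: list[np.ndarray]
    alpha: float
    method: str
    labels: list = field(default_factory=list)

    @property
    def n_individual_rejections(self) -> int:
        return int(sum(r.sum() for r in self.individual_rejected))

    def set_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": self.labels,
                "screening_p": self.screening.p0,
                "set_rejected": self.screening.rejected,
                "n_rejected": [int(r.sum()) for r in self.individual_rejected],
            }
        )

    def hypothesis_table(self) -> pd.DataFrame:
        rows = []
        for i, label in enumerate(self.labels):
            for j in range(self.individual_rejected[i].size):
                rows.append(
                    (label, j + 1, bool(self.individual_rejected[i][j]), int(self.direction[i][j]))
                )
        return pd.DataFrame(rows, columns=["set_id", "hypothesis_id", "rejected", "direction"])

    def summary(self) -> str:
        m = self.screening.p0.size
        lines = [
            "Two-step hierarchical hypothesis-set test"
            if self.method != "simple_bh"
            else "Pooled one-step Benjamini-Hochberg test",
            f"  method: {self.method}    alpha: {self.alpha:g}",
            f"  hypothesis sets:        {m}",
            f"  sets rejected (R):      {self.screening.R}",
            f"  individual rejections:  {self.n_individual_rejections}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# screening p-values


def screening_pvalue_bonferroni(p: np.ndarray) -> float:
    """Bonferroni screening p-value ``min(1, n * min(p))``.

    Used by the Bonferroni- and Holm-based procedures; testing it against the
    BH threshold is equivalent to testing the smallest individual p-value at
    a 1/n fraction of that threshold.
    """
    p = _validate_pvector(p)
    return float(min(1.0, p.size * p.min()))


def screening_pvalue_hochberg(p: np.ndarray) -> float:
    """Hochberg screening p-value ``min_j (n + 1 - j) * p_(j)``, clipped to 1.

    Never exceeds the Bonferroni screening p-value (the j = 1 term is the
    Bonferroni value), so the Hochberg-based procedure screens in at least
    as many sets.
    """
    p = _validate_pvector(p)
    ps = np.sort(p)
    coef = np.arange(p.size, 0, -1)  # n + 1 - j for j = 1..n
    return float(min(1.0, (coef * ps).min()))


def _screening_pvalues(collection: PValueSetCollection, method: str) -> np.ndarray:
    if method in ("bonferroni", "holm"):
        return np.array([screening_pvalue_bonferroni(v) for v in collection.p])
    if method == "hochberg":
        return np.array([screening_pvalue_hochberg(v) for v in collection.p])
    raise ValueError(f"unknown method {method!r}")


def _screening_pvalues_matrix(P: np.ndarray, method: str) -> np.ndarray:
    """Vectorized screening p-values for an (m, q) p-value matrix."""
    q = P.shape[1]
    if method in ("bonferroni", "holm"):
        return np.minimum(1.0, q * P.min(axis=1))
    S = np.sort(P, axis=1)
    coef = np.arange(q, 0, -1)
    return np.minimum(1.0, (coef * S).min(axis=1))


# ---------------------------------------------------------------------------
# BH step-up


def bh_step_up(p0: np.ndarray, alpha: float) -> ScreeningResult:
    """Benjamini–Hochberg step-up at level ``alpha``.

    With ordered p-values ``p_(1) <= ... <= p_(m)``, rejects the R smallest
    where ``R = max{k : p_(k) <= k * alpha / m}`` (R = 0 if no k qualifies);
    equivalently every p-value ``<= R * alpha / m`` is rejected.
    """
    p0 = _validate_pvector(p0, "p0")
    alpha = _validate_alpha(alpha)
    m = p0.size
    ps = np.sort(p0)
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ps <= thresholds)
    R = int(passing[-1] + 1) if passing.size else 0
    rejected = p0 <= (R * alpha / m) if R > 0 else np.zeros(m, dtype=bool)
    return ScreeningResult(p0=p0, rejected=rejected, R=R, alpha=alpha)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up q-values), monotone and clipped to 1."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# second-stage FWER procedures


def second_stage_rule(p: np.ndarray, level: float, method: str) -> SecondStageRule:
    """Compute the step index of Holm/Hochberg (Bonferroni has none).

    Holm (step-down): largest j such that ``p_(l) <= level / (n + 1 - l)`` for
    every ``l <= j``.  Hochberg (step-up): largest j such that
    ``p_(j) <= level / (n + 1 - j)``.  Both then reject every hypothesis with
    ``p <= p_(j)``.
    """
    p = _validate_pvector(p)
    n = p.size
    ps = np.sort(p)
    ok = ps <= level / np.arange(n, 0, -1)
    if method == "holm":
        bad = np.flatnonzero(~ok)
        r = int(bad[0]) if bad.size else n
    elif method == "hochberg":
        idx = np.flatnonzero(ok)
        r = int(idx[-1] + 1) if idx.size else 0
    else:
        raise ValueError(f"no step rule for method {method!r}")
    return SecondStageRule(within_set_level=level, n=n, r=r)


def second_stage(p: np.ndarray, level: float, method: str) -> np.ndarray:
    """Rejections of one FWER procedure at the given level within one set.

    Bonferroni rejects ``p_j <= level / n``; Holm and Hochberg reject
    ``p_j <= p_(r)`` where ``r`` is their respective step index (nothing if
    r = 0).  At equal level the rejection sets are nested:
    Bonferroni ⊆ Holm ⊆ Hochberg.
    """
    p = _validate_pvector(p)
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must lie in (0, 1], got {level}")
    if method == "bonferroni":
        return p <= level / p.size
    if method in ("holm", "hochberg"):
        rule = second_stage_rule(p, level, method)
        if rule.r == 0:
            return np.zeros(p.size, dtype=bool)
        cutoff = np.sort(p)[rule.r - 1]
        return p <= cutoff
    raise ValueError(f"unknown second-stage method {method!r}")


def _second_stage_matrix(P: np.ndarray, level: float, method: str) -> np.ndarray:
    """Vectorized `second_stage` over the rows of an (k, q) matrix."""
    k, q = P.shape
    if method == "bonferroni":
        return P <= level / q
    S = np.sort(P, axis=1)
    ok = S <= level / np.arange(q, 0, -1)
    if method == "holm":
        r = np.cumprod(ok, axis=1).sum(axis=1)
    elif method == "hochberg":
        any_ok = ok.any(axis=1)
        r = np.where(any_ok, q - np.argmax(ok[:, ::-1], axis=1), 0)
    else:
        raise ValueError(f"unknown second-stage method {method!r}")
    cutoff = np.where(r > 0, S[np.arange(k), np.maximum(r, 1) - 1], -1.0)
    return P <= cutoff[:, None]


# ---------------------------------------------------------------------------
# assembled procedures


def _directions(
    individual_rejected: list[np.ndarray], signs: list[np.ndarray]
) -> list[np.ndarray]:
    out = []
    zero_sign_rejections = 0
    for rej, s in zip(individual_rejected, signs):
        zero_sign_rejections += int(np.sum(rej & (s == 0)))
        out.append(np.where(rej, s, 0).astype(int))
    if zero_sign_rejections:
        warnings.warn(
            f"{zero_sign_rejections} rejected hypothesis(es) have a zero test "
            "statistic; no direction is declared for them",
            UserWarning,
            stacklevel=3,
        )
    return out


def run_two_step(
    collection: PValueSetCollection, alpha: float, method: str = "hochberg"
) -> DecisionReport:
    """Run the two-step set-testing procedure with the named FWER method.

    Step 1 screens the m sets with BH at level ``alpha`` applied to the
    per-set screening p-values (Bonferroni formula for methods ``bonferroni``
    and ``holm``, Hochberg formula for ``hochberg``).  Step 2 runs the named
    FWER procedure at level ``R * alpha / m`` inside each rejected set.
    Directions of rejected hypotheses are the signs of their test statistics.
    If R = 0 the second stage is skipped and nothing is rejected.
    """
    alpha = _validate_alpha(alpha)
    if method not in TWO_STEP_METHODS:
        raise ValueError(
            f"method must be one of {TWO_STEP_METHODS} for the two-step procedure, got {method!r}"
        )
    m = collection.n_sets
    if collection.is_uniform:
        P, S = collection.as_matrices()
        p0 = _screening_pvalues_matrix(P, method)
        screening = bh_step_up(p0, alpha)
        rej2d = np.zeros(P.shape, dtype=bool)
        if screening.R > 0:
            level = screening.R * alpha / m
            idx = np.flatnonzero(screening.rejected)
            rej2d[idx] = _second_stage_matrix(P[idx], level, method)
        n_zero_sign = int(np.sum(rej2d & (S == 0)))
        if n_zero_sign:
            warnings.warn(
                f"{n_zero_sign} rejected hypothesis(es) have a zero test "
                "statistic; no direction is declared for them",
                UserWarning,
                stacklevel=2,
            )
        individual_rejected = list(rej2d)
        direction = list(np.where(rej2d, S, 0).astype(int))
    else:
        p0 = _screening_pvalues(collection, method)
        screening = bh_step_up(p0, alpha)
        individual_rejected = [np.zeros(v.size, dtype=bool) for v in collection.p]
        if screening.R > 0:
            level = screening.R * alpha / m
            for i in np.flatnonzero(screening.rejected):
                individual_rejected[i] = second_stage(collection.p[i], level, method)
        direction = _directions(individual_rejected, collection.sign)
    return DecisionReport(
        screening=screening,
        individual_rejected=individual_rejected,
        direction=direction,
        alpha=alpha,
        method=method,
        labels=collection.labels,
    )


def run_simple_bh(collection: PValueSetCollection, alpha: float) -> DecisionReport:
    """One-step comparator: pooled BH over all individual hypotheses.

    All ``sum_i n(i)`` individual p-values are tested together with BH at
    level ``alpha``; a set counts as rejected when any of its hypotheses is
    rejected.  This controls the FDR of the individual hypotheses but not the
    set-wise OFDR/mdFDR, and always rejects at least as many sets as the
    Bonferroni-based two-step procedure at the same level.
    """
    alpha = _validate_alpha(alpha)
    if collection.is_uniform:
        P, S = collection.as_matrices()
        m, q = P.shape
        result = bh_step_up(P.ravel(), alpha)
        rej2d = result.rejected.reshape(m, q)
        set_rejected = rej2d.any(axis=1)
        # No screening p-value exists for the pooled procedure; report the
        # smallest BH-adjusted p-value per set so rejected(i) <=> p0(i) <= alpha.
        p0 = _bh_adjust(P.ravel()).reshape(m, q).min(axis=1)
        individual_rejected = list(rej2d)
        direction = list(np.where(rej2d, S, 0).astype(int))
    else:
        sizes = collection.sizes
        pooled = np.concatenate(collection.p)
        result = bh_step_up(pooled, alpha)
        splits = np.cumsum(sizes)[:-1]
        individual_rejected = [r.copy() for r in np.split(result.rejected, splits)]
        set_rejected = np.array([r.any() for r in individual_rejected])
        adjusted = _bh_adjust(pooled)
        p0 = np.array([a.min() for a in np.split(adjusted, splits)])
        direction = _directions(individual_rejected, collection.sign)
    screening = ScreeningResult(
        p0=p0, rejected=set_rejected, R=int(set_rejected.sum()), alpha=alpha
    )
    return DecisionReport(
        screening=screening,
        individual_rejected=individual_rejected,
        direction=direction,
        alpha=alpha,
        method="simple_bh",
        labels=collection.labels,
    )


def run_procedure(collection: PValueSetCollection, alpha: float, method: str) -> DecisionReport:
    """Dispatch to `run_two_step` or `run_simple_bh` by method name."""
    if method == "simple_bh":
        return run_simple_bh(collection, alpha)
    return run_two_step(collection, alpha, method)
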
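"""Ground-truth error and power metrics for hypothesis-set decisions.

Definitions, for one replication with known truth:

* ``R`` — number of rejected hypothesis sets.
* ``V`` — number of *falsely* rejected sets: rejected sets in which at least
  one true null (the screening null included — a rejected set with no false
  individual null is false by definition) was rejected.
* ``S`` — number of sets rejected correctly (not in V) but carrying at least
  one directional error among their rejected individual hypotheses.

OFDR = E[V / max(R, 1)] and mdFDR = E[(V + S) / max(R, 1)]; V and S are
disjoint, so OFDR <= mdFDR holds replication by replication.

Power (I) is the proportion of false individual nulls correctly rejected;
power (II) the proportion of false-null sets for which every within-set
decision — rejection status and declared direction — is correct.  By default
a false null rejected with the wrong sign does not count as a success for
either power; pass ``require_direction=False`` for the sign-agnostic reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import DecisionReport

__all__ = [
    "TruthSpec",
    "ErrorPowerEstimates",
    "ReplicationMetrics",
    "count_errors",
    "ofdr",
    "mdfdr",
    "power_individual",
    "power_setwise",
    "evaluate",
]


@dataclass
class TruthSpec:
    """Ground truth for a collection of hypothesis sets.

    ``false_null[i][j]`` is True iff individual null j of set i is false;
    ``true_sign[i][j]`` is the sign of the true effect (0 where the null is
    true).  A set's screening null is false iff any individual null in it is.
    """

    false_null: list[np.ndarray]
    true_sign: list[np.ndarray]

    def __init__(self, false_null, true_sign):
        self._FN = self._TS = None  # cached rectangular form, when one exists
        if (
            isinstance(false_null, np.ndarray)
            and false_null.ndim == 2
            and isinstance(true_sign, np.ndarray)
            and true_sign.ndim == 2
        ):
            FN = np.asarray(false_null, dtype=bool)
            TS = np.sign(np.asarray(true_sign)).astype(int)
            if FN.shape != TS.shape:
                raise ValueError("false_null and true_sign shapes differ")
            if not np.array_equal(FN, TS != 0):
                raise ValueError("false_null must coincide with true_sign != 0")
            self._FN, self._TS = FN, TS
            self.false_null = list(FN)
            self.true_sign = list(TS)
            return
        if isinstance(false_null, np.ndarray) and false_null.ndim == 2:
            false_null = list(false_null)
        if isinstance(true_sign, np.ndarray) and true_sign.ndim == 2:
            true_sign = list(true_sign)
        self.false_null = [np.asarray(f, dtype=bool) for f in false_null]
        self.true_sign = [np.sign(np.asarray(s)).astype(int) for s in true_sign]
        if len(self.false_null) != len(self.true_sign):
            raise ValueError("false_null and true_sign must have the same number of sets")
        for i, (f, s) in enumerate(zip(self.false_null, self.true_sign)):
            if f.shape != s.shape:
                raise ValueError(f"shape mismatch in set {i}")
            if not np.array_equal(f, s != 0):
                raise ValueError(
                    f"set {i}: false_null must coincide with true_sign != 0"
                )

    @classmethod
    def from_signs(cls, true_sign) -> "TruthSpec":
        if isinstance(true_sign, np.ndarray) and true_sign.ndim == 2:
            signs = np.sign(true_sign).astype(int)
            return cls(signs != 0, signs)
        signs = [np.sign(np.asarray(s)).astype(int) for s in true_sign]
        return cls([s != 0 for s in signs], signs)

    def as_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, q) false-null and true-sign matrices; needs a constant set size."""
        if self._FN is None:
            sizes = {f.size for f in self.false_null}
            if len(sizes) != 1:
                raise ValueError("set sizes vary; no rectangular representation exists")
            self._FN = np.vstack(self.false_null)
            self._TS = np.vstack(self.true_sign)
        return self._FN, self._TS

    @property
    def n_sets(self) -> int:
        return len(self.false_null)

    @property
    def set_false_null(self) -> np.ndarray:
        if self._FN is not None:
            return self._FN.any(axis=1)
        return np.array([f.any() for f in self.false_null])

    @property
    def n_false_individual(self) -> int:
        if self._FN is not None:
            return int(self._FN.sum())
        return int(sum(f.sum() for f in self.false_null))


def _check_shapes(report: DecisionReport, truth: TruthSpec) -> None:
    if len(report.individual_rejected) != truth.n_sets:
        raise ValueError("report and truth differ in the number of sets")
    rep_sizes = np.fromiter(
        (r.size for r in report.individual_rejected), dtype=int, count=truth.n_sets
    )
    truth_sizes = np.fromiter(
        (f.size for f in truth.false_null), dtype=int, count=truth.n_sets
    )
    if not np.array_equal(rep_sizes, truth_sizes):
        i = int(np.flatnonzero(rep_sizes != truth_sizes)[0])
        raise ValueError(f"report and truth differ in the size of set {i}")


def count_errors(report: DecisionReport, truth: TruthSpec) -> tuple[int, int, int]:
    """Count (R, V, S) for one replication.

    A rejected set falls in V when a true null within it was rejected — which
    includes the screening null itself, so a rejected set containing no false
    individual null is in V regardless of its individual rejections.  A
    rejected set not in V falls in S when some rejected (necessarily false
    null) hypothesis carries the wrong declared direction.
    """
    _check_shapes(report, truth)
    set_rej = report.screening.rejected
    R = int(set_rej.sum())
    V = 0
    S = 0
    for i in np.flatnonzero(set_rej):
        rej = report.individual_rejected[i]
        fn = truth.false_null[i]
        if not fn.any() or np.any(rej & ~fn):
            V += 1
        elif np.any(rej & fn & (report.direction[i] != truth.true_sign[i])):
            S += 1
    return R, V, S


def ofdr(R: int, V: int) -> float:
    """Per-replication overall false discovery proportion V / max(R, 1)."""
    if V < 0 or R < 0 or V > max(R, 1):
        raise ValueError("require 0 <= V <= R (or R = 0 with V = 0)")
    return V / max(R, 1)


def mdfdr(R: int, V: int, S: int) -> float:
    """Per-replication mixed-directional proportion (V + S) / max(R, 1)."""
    if min(R, V, S) < 0 or (V + S > R and R > 0) or (R == 0 and V + S > 0):
        raise ValueError("require V + S <= R (or R = 0 with V = S = 0)")
    return (V + S) / max(R, 1)


def power_individual(
    report: DecisionReport, truth: TruthSpec, require_direction: bool = True
) -> float:
    """Power (I): proportion of false individual nulls correctly rejected."""
    _check_shapes(report, truth)
    n_false = truth.n_false_individual
    if n_false == 0:
        raise ValueError("power is undefined: no false individual nulls in the truth")
    hits = 0
    for rej, d, fn, ts in zip(
        report.individual_rejected, report.direction, truth.false_null, truth.true_sign
    ):
        good = rej & fn
        if require_direction:
            good &= d == ts
        hits += int(good.sum())
    return hits / n_false


def power_setwise(
    report: DecisionReport, truth: TruthSpec, require_direction: bool = True
) -> float:
    """Power (II): proportion of false-null sets with entirely correct decisions.

    A false-null set counts only when every false individual null is rejected
    (with the correct declared direction unless ``require_direction=False``)
    and no true individual null is rejected.
    """
    _check_shapes(report, truth)
    false_sets = np.flatnonzero(truth.set_false_null)
    if false_sets.size == 0:
        raise ValueError("power is undefined: no false-null sets in the truth")
    hits = 0
    for i in false_sets:
        rej = report.individual_rejected[i]
        fn = truth.false_null[i]
        if np.any(rej & ~fn):
            continue
        if not np.all(rej[fn]):
            continue
        if require_direction and not np.all(
            report.direction[i][fn] == truth.true_sign[i][fn]
        ):
            continue
        hits += 1
    return hits / false_sets.size


class ReplicationMetrics(NamedTuple):
    """All per-replication quantities in one pass; powers are NaN when undefined."""

    R: int
    V: int
    S: int
    ofdr: float
    mdfdr: float
    power_i: float
    power_ii: float


def evaluate(
    report: DecisionReport, truth: TruthSpec, require_direction: bool = True
) -> ReplicationMetrics:
    """Compute (R, V, S), error proportions and both powers for one replication.

    Uses a vectorized path when all sets share a size (the simulation case);
    otherwise defers to the per-set counting functions.  Unlike
    `power_individual`/`power_setwise`, a truth with no false nulls yields NaN
    powers instead of raising, so Monte-Carlo sweeps can include the complete
    null configuration.
    """
    _check_shapes(report, truth)
    sizes = {f.size for f in truth.false_null}
    if len(sizes) == 1:
        set_rej = report.screening.rejected
        rej = np.vstack(report.individual_rejected)
        direc = np.vstack(report.direction)
        fn, ts = truth.as_matrices()

        R = int(set_rej.sum())
        false_rej = (rej & ~fn).any(axis=1)
        set_fn = fn.any(axis=1)
        in_v = set_rej & (~set_fn | false_rej)
        dir_err = (rej & fn & (direc != ts)).any(axis=1)
        in_s = set_rej & ~in_v & dir_err
        V, S = int(in_v.sum()), int(in_s.sum())

        n_false = int(fn.sum())
        if n_false:
            good = rej & fn
            if require_direction:
                good &= direc == ts
            p_i = float(good.sum() / n_false)
            all_false_hit = (good | ~fn).all(axis=1)
            correct = ~false_rej & all_false_hit
            p_ii = float((set_fn & correct).sum() / set_fn.sum())
        else:
            p_i = p_ii = float("nan")
    else:
        R, V, S = count_errors(report, truth)
        if truth.n_false_individual:
            p_i = power_individual(report, truth, require_direction)
            p_ii = power_setwise(report, truth, require_direction)
        else:
            p_i = p_ii = float("nan")
    return ReplicationMetrics(
        R=R, V=V, S=S, ofdr=ofdr(R, V), mdfdr=mdfdr(R, V, S), power_i=p_i, power_ii=p_ii
    )


@dataclass
class ErrorPowerEstimates:
    """Monte-Carlo estimates of OFDR, mdFDR and both powers with SEs.

    Aggregation is the mean of per-replication proportions (matching the
    defining expectations); standard errors are sample SD / sqrt(n_reps).
    Power entries are NaN when a replication has no false nulls.
    """

    method: str
    ofdr: float
    mdfdr: float
    power_i: float
    power_ii: float
    se_ofdr: float
    se_mdfdr: float
    se_power_i: float
    se_power_ii: float
    n_reps: int
    per_rep: dict[str, np.ndarray] | None = None

    @classmethod
    def from_replications(
        cls,
        method: str,
        ofdr_vals: np.ndarray,
        mdfdr_vals: np.ndarray,
        power_i_vals: np.ndarray,
        power_ii_vals: np.ndarray,
        keep_reps: bool = False,
    ) -> "ErrorPowerEstimates":
        def agg(x):
            x = np.asarray(x, dtype=float)
            if np.all(np.isnan(x)):
                return float("nan"), float("nan")
            n = np.sum(~np.isnan(x))
            mean = float(np.nanmean(x))
            se = float(np.nanstd(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            return mean, se

        o, se_o = agg(ofdr_vals)
        d, se_d = agg(mdfdr_vals)
        pi, se_pi = agg(power_i_vals)
        pii, se_pii = agg(power_ii_vals)
        per_rep = None
        if keep_reps:
            per_rep = {
                "ofdr": np.asarray(ofdr_vals, dtype=float),
                "mdfdr": np.asarray(mdfdr_vals, dtype=float),
                "power_i": np.asarray(power_i_vals, dtype=float),
                "power_ii": np.asarray(power_ii_vals, dtype=float),
            }
        return cls(
            method=method,
            ofdr=o, mdfdr=d, power_i=pi, power_ii=pii,
            se_ofdr=se_o, se_mdfdr=se_d, se_power_i=se_pi, se_power_ii=se_pii,
            n_reps=int(np.asarray(ofdr_vals).size),
            per_rep=per_rep,
        )
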
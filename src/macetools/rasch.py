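"""Dichotomous (one-parameter logistic) Rasch model.

The measurement model underlying every MACE subscale: the probability
that person *n* endorses item *i* depends only on the difference between
the person's latent exposure level ``theta_n`` and the item's severity
(difficulty) ``b_i``,

    P(x_ni = 1) = exp(theta_n - b_i) / (1 + exp(theta_n - b_i)).

This module provides the probability model, item-difficulty estimation
by conditional maximum likelihood (the default; invariant to the person
distribution) or joint "unconditional" maximum likelihood, person
parameter estimation from raw scores, and item/test information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ItemBank",
    "ResponseMatrix",
    "PersonEstimate",
    "icc_probability",
    "item_information",
    "test_information",
    "estimate_person_theta",
    "theta_by_raw_score",
    "estimate_item_difficulties",
    "conditional_log_likelihood",
    "log_esf",
]

# Numerical policy shared by the estimation routines.
MAX_ITER = 500
LOGLIK_RTOL = 1e-10
ROOT_XTOL = 1e-8
BRACKET_START = 10.0  # root brackets expand geometrically from [-10, 10]
EXTREME_SCORE_ADJUST = 0.25  # r -> r +/- 0.25 convention for extreme scores


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ItemBank:
    """A calibrated set of items: ids, difficulties (logits) and SEs.

    When ``normalized`` is set the difficulties are mean-centered
    (sum-to-zero gauge); published banks satisfy this within rounding.
    ``anchor_low``/``anchor_high`` optionally carry the instrument's
    extreme-score logits (theta at raw score 0 and k).
    """

    item_ids: list
    difficulty: np.ndarray
    difficulty_se: np.ndarray | None = None
    normalized: bool = True
    anchor_low: float | None = None
    anchor_high: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.item_ids = list(self.item_ids)
        self.difficulty = _as_finite_array(self.difficulty, "difficulty")
        if len(self.item_ids) != self.difficulty.size:
            raise ValueError("item_ids and difficulty length mismatch")
        if self.difficulty_se is not None:
            se = np.asarray(self.difficulty_se, dtype=float)
            if np.any(se[np.isfinite(se)] <= 0):
                raise ValueError("difficulty_se must be positive where present")
            self.difficulty_se = se
        if self.normalized and abs(float(self.difficulty.sum())) > 0.02:
            raise ValueError(
                "normalized bank difficulties must sum to 0 within 0.02, "
                f"got {self.difficulty.sum():.4f}"
            )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_records(self) -> list[dict]:
        out = []
        for j, item in enumerate(self.item_ids):
            se = None
            if self.difficulty_se is not None and np.isfinite(self.difficulty_se[j]):
                se = float(self.difficulty_se[j])
            out.append({"item_id": item, "difficulty": float(self.difficulty[j]), "se": se})
        return out


@dataclass
class ResponseMatrix:
    """Persons x items binary responses with a missing mask.

    ``values`` is a float array with entries 0, 1 or NaN (missing).
    ``ages`` optionally maps (person_index, item_index) -> set of endorsed
    ages in 1..18; age sets may only be attached to endorsed (1) cells.
    """

    persons: list
    items: list
    values: np.ndarray
    ages: dict | None = None

    def __post_init__(self):
        self.persons = list(self.persons)
        self.items = list(self.items)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.persons), len(self.items)):
            raise ValueError("values shape does not match persons x items")
        obs = vals[~np.isnan(vals)]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            raise ValueError("non-missing responses must be 0 or 1")
        self.values = vals
        if self.ages:
            for (p, i), ages in self.ages.items():
                if not ages:
                    continue
                if vals[p, i] != 1.0:
                    raise ValueError(
                        f"age set attached to non-endorsed cell ({self.persons[p]}, {self.items[i]})"
                    )
                if any((a < 1 or a > 18 or int(a) != a) for a in ages):
                    raise ValueError(f"ages must be integers in 1..18, got {sorted(ages)}")

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def raw_scores(self) -> np.ndarray:
        """Per-person count of endorsed items over *observed* cells."""
        return np.nansum(self.values, axis=1)

    def observed_counts(self) -> np.ndarray:
        return self.observed_mask().sum(axis=1)

    def item_observation_counts(self) -> np.ndarray:
        return self.observed_mask().sum(axis=0)

    def subset_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.items.index(i) for i in item_ids]
        ages = None
        if self.ages is not None:
            pos = {orig: new for new, orig in enumerate(idx)}
            ages = {
                (p, pos[i]): a for (p, i), a in self.ages.items() if i in pos
            }
        return ResponseMatrix(self.persons, [self.items[i] for i in idx],
                              self.values[:, idx], ages)

    def drop_persons(self, keep_mask: np.ndarray) -> "ResponseMatrix":
        keep_idx = np.flatnonzero(keep_mask)
        remap = {orig: new for new, orig in enumerate(keep_idx)}
        ages = None
        if self.ages is not None:
            ages = {
                (remap[p], i): a for (p, i), a in self.ages.items() if p in remap
            }
        return ResponseMatrix([self.persons[i] for i in keep_idx], self.items,
                              self.values[keep_idx], ages)


@dataclass
class PersonEstimate:
    """ML person parameter at a given raw score on a fixed bank."""

    raw_score: int
    theta: float
    theta_se: float
    extreme: bool
    convention: str = "ml"  # "ml", "anchor" or "adjusted" (r +/- 0.25)


# ---------------------------------------------------------------------------
# Probability model and information
# ---------------------------------------------------------------------------


def icc_probability(theta, b):
    """Item characteristic curve: P(endorse | theta, b) = expit(theta - b).

    Monotone increasing in ``theta`` and decreasing in ``b``; equals 0.5
    at ``theta == b``. Vectorizes over either argument.
    """
    t = _as_finite_array(theta, "theta")
    d = _as_finite_array(b, "b")
    out = expit(t - d)
    return float(out) if out.ndim == 0 else out


def item_information(theta, b):
    """Fisher information of one item: P(1-P); maximal (0.25) at theta == b."""
    p = icc_probability(theta, b)
    return p * (1.0 - p)


def test_information(theta, bank: ItemBank):
    """Test information function: sum of item informations over the bank.

    Equals the negative second derivative of the person log-likelihood,
    hence ``1/sqrt(TI)`` is the asymptotic SE of the person estimate.
    """
    t = _as_finite_array(theta, "theta")
    p = expit(t[..., None] - bank.difficulty) if t.ndim else expit(t - bank.difficulty)
    info = (p * (1.0 - p)).sum(axis=-1)
    return float(info) if np.ndim(info) == 0 else info


# ---------------------------------------------------------------------------
# Person parameter estimation
# ---------------------------------------------------------------------------


def _solve_expected_score(target: float, difficulty: np.ndarray) -> float:
    """Solve sum_i expit(theta - b_i) == target by bracketed root-finding."""

    def f(theta):
        return float(expit(theta - difficulty).sum() - target)

    lo, hi = -BRACKET_START, BRACKET_START
    while f(lo) > 0:
        lo *= 2.0
        if lo < -1e6:  # pragma: no cover - target must be in (0, k)
            raise RuntimeError("bracket expansion failed (low side)")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise RuntimeError("bracket expansion failed (high side)")
    return brentq(f, lo, hi, xtol=ROOT_XTOL)


def estimate_person_theta(r: int, bank: ItemBank) -> PersonEstimate:
    """ML person logit for raw score ``r`` on ``bank``.

    For 0 < r < k, theta solves sum_i P(theta, b_i) = r (the ML equation;
    the raw score is sufficient under the Rasch model). Extreme scores
    (r = 0 or r = k) have no finite ML solution: published anchors are
    used verbatim when the bank carries them, otherwise the conventional
    r -> r +/- 0.25 adjustment is applied and recorded.
    """
    k = bank.n_items
    if not (isinstance(r, (int, np.integer)) or float(r).is_integer()):
        raise ValueError(f"raw score must be an integer, got {r!r}")
    r = int(r)
    if r < 0 or r > k:
        raise ValueError(f"raw score {r} outside [0, {k}]")

    if 0 < r < k:
        theta = _solve_expected_score(r, bank.difficulty)
        se = 1.0 / math.sqrt(test_information(theta, bank))
        return PersonEstimate(r, theta, se, extreme=False, convention="ml")

    anchor = bank.anchor_low if r == 0 else bank.anchor_high
    if anchor is not None:
        return PersonEstimate(r, float(anchor), math.nan, extreme=True,
                              convention="anchor")
    target = EXTREME_SCORE_ADJUST if r == 0 else k - EXTREME_SCORE_ADJUST
    theta = _solve_expected_score(target, bank.difficulty)
    return PersonEstimate(r, theta, math.nan, extreme=True, convention="adjusted")


def theta_by_raw_score(bank: ItemBank) -> dict:
    """Person estimates for every raw score 0..k on the bank."""
    return {r: estimate_person_theta(r, bank) for r in range(bank.n_items + 1)}


# ---------------------------------------------------------------------------
# Elementary symmetric functions (log space)
# ---------------------------------------------------------------------------


def log_esf(log_eps: np.ndarray) -> np.ndarray:
    """Log elementary symmetric functions of exp(log_eps).

    Returns an array g of length k+1 with g[r] = log gamma_r, computed by
    the summation algorithm (one item folded in at a time), which is
    numerically stable in log space.
    """
    k = log_eps.size
    g = np.full(k + 1, -np.inf)
    g[0] = 0.0
    for j in range(k):
        # fold item j in: gamma_r <- gamma_r + eps_j * gamma_{r-1}
        g[1 : j + 2] = np.logaddexp(g[1 : j + 2], g[0 : j + 1] + log_eps[j])
    return g


def _log_esf_without(log_eps: np.ndarray) -> np.ndarray:
    """Leave-one-out log ESFs: row i holds log gamma_r of all items but i."""
    k = log_eps.size
    out = np.empty((k, k), dtype=float)  # orders 0..k-1
    for i in range(k):
        out[i] = log_esf(np.delete(log_eps, i))
    return out


# ---------------------------------------------------------------------------
# Conditional maximum likelihood
# ---------------------------------------------------------------------------


class _PatternGroup:
    """Sufficient statistics for persons sharing one observed-item pattern."""

    def __init__(self, observed_idx: np.ndarray, sub_values: np.ndarray):
        self.observed_idx = observed_idx  # indices into the full item list
        k = observed_idx.size
        r = sub_values.sum(axis=1).astype(int)
        keep = (r > 0) & (r < k)  # extreme scores carry no conditional info
        sub = sub_values[keep]
        self.n_used = int(keep.sum())
        self.item_totals = sub.sum(axis=0)  # s_i over retained persons
        self.score_counts = np.bincount(r[keep], minlength=k + 1).astype(float)

    @property
    def k(self) -> int:
        return self.observed_idx.size


def _pattern_groups(data: ResponseMatrix) -> list[_PatternGroup]:
    mask = data.observed_mask()
    groups: dict[bytes, list[int]] = {}
    for n in range(data.n_persons):
        key = mask[n].tobytes()
        groups.setdefault(key, []).append(n)
    out = []
    for rows in groups.values():
        obs = np.flatnonzero(mask[rows[0]])
        if obs.size < 2:
            continue
        sub = data.values[np.ix_(rows, obs)]
        g = _PatternGroup(obs, sub)
        if g.n_used:
            out.append(g)
    return out


def conditional_log_likelihood(b: np.ndarray, groups: list[_PatternGroup],
                               with_grad: bool = False):
    """Conditional log-likelihood of item difficulties given raw scores.

    Persons with extreme raw scores contribute a constant (their pattern
    is fully determined by the score) and are excluded. The gradient is
    the classic CML score function: E[x_ni | r_n] - x_ni summed over
    persons, expressed through leave-one-out ESFs.
    """
    ll = 0.0
    grad = np.zeros_like(b) if with_grad else None
    for g in groups:
        bg = b[g.observed_idx]
        log_eps = -bg
        lg = log_esf(log_eps)
        rs = np.flatnonzero(g.score_counts)  # raw scores present (non-extreme)
        ll -= float(g.item_totals @ bg)
        ll -= float(g.score_counts[rs] @ lg[rs])
        if with_grad:
            loo = _log_esf_without(log_eps)  # (k, k): orders 0..k-1
            # conditional expectation of x_i at raw score r:
            #   eps_i * gamma_{r-1}^{(\i)} / gamma_r
            cond = np.zeros(g.k)
            for r in rs:
                log_p = log_eps + loo[:, r - 1] - lg[r]
                cond += g.score_counts[r] * np.exp(log_p)
            grad[g.observed_idx] += -g.item_totals + cond
    return (ll, grad) if with_grad else ll


def _check_item_variance(data: ResponseMatrix):
    """Reject items endorsed by all or none of the non-extreme persons."""
    mask = data.observed_mask()
    r = data.raw_scores()
    k_obs = data.observed_counts()
    nonextreme = (r > 0) & (r < k_obs)
    if not nonextreme.any():
        raise ValueError("no persons with non-extreme raw scores; cannot calibrate")
    for j, item in enumerate(data.items):
        rows = nonextreme & mask[:, j]
        vals = data.values[rows, j]
        if vals.size == 0 or np.all(vals == vals[0] if vals.size else True):
            raise ValueError(
                f"item {item!r} has no variance among non-extreme persons; "
                "its difficulty diverges (all-or-none endorsement)"
            )


def _cml_fit(data: ResponseMatrix):
    groups = _pattern_groups(data)
    if not groups:
        raise ValueError("no usable response patterns (need >=2 observed items "
                         "and non-extreme scores)")
    k = data.n_items

    # sum-zero gauge: optimize k-1 free parameters, b_k = -sum(others)
    basis = np.vstack([np.eye(k - 1), -np.ones(k - 1)])  # (k, k-1)

    def objective(u):
        b = basis @ u
        ll, g = conditional_log_likelihood(b, groups, with_grad=True)
        return -ll, -(basis.T @ g)

    res = minimize(objective, np.zeros(k - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": MAX_ITER, "ftol": LOGLIK_RTOL,
                            "gtol": 1e-9})
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise RuntimeError(
            f"conditional ML did not converge after {res.nit} iterations: "
            f"{res.message} (|grad|={np.linalg.norm(res.jac):.2e})"
        )
    u = res.x
    b = basis @ u

    # observed information: finite differences of the analytic gradient
    h = 1e-5
    hess = np.zeros((k - 1, k - 1))
    for j in range(k - 1):
        up = u.copy(); up[j] += h
        dn = u.copy(); dn[j] -= h
        _, gp = objective(up)
        _, gn = objective(dn)
        hess[:, j] = (gp - gn) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    try:
        cov_u = np.linalg.inv(hess)
        cov_b = basis @ cov_u @ basis.T
        se = np.sqrt(np.clip(np.diag(cov_b), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular designs
        se = np.full(k, np.nan)
    return b, se, float(-res.fun), int(res.nit)


def _jml_fit(data: ResponseMatrix):
    """Joint ("unconditional") ML: alternate person and item updates."""
    mask = data.observed_mask()
    x = np.where(mask, data.values, 0.0)
    r = data.raw_scores()
    k_obs = data.observed_counts()
    nonextreme = (r > 0) & (r < k_obs)
    X = x[nonextreme]
    M = mask[nonextreme]
    rr = r[nonextreme]

    k = data.n_items
    b = np.zeros(k)
    theta = np.zeros(nonextreme.sum())
    last_ll = -np.inf
    for it in range(MAX_ITER):
        # person step: solve sum_{i observed} P = r per person (Newton)
        for _ in range(50):
            p = expit(theta[:, None] - b[None, :]) * M
            f = p.sum(axis=1) - rr
            w = (p * (1 - p)).sum(axis=1)
            step = f / np.maximum(w, 1e-12)
            theta -= np.clip(step, -2, 2)
            if np.max(np.abs(f)) < 1e-10:
                break
        # item step: solve sum_n P_ni = s_i per item (Newton)
        for _ in range(50):
            p = expit(theta[:, None] - b[None, :]) * M
            s = (X * M).sum(axis=0)
            f = p.sum(axis=0) - s
            w = (p * (1 - p)).sum(axis=0)
            step = f / np.maximum(w, 1e-12)
            b += np.clip(step, -2, 2)
            if np.max(np.abs(f)) < 1e-10:
                break
        b -= b.mean()
        p = expit(theta[:, None] - b[None, :])
        with np.errstate(divide="ignore"):
            ll = float(np.sum(M * (X * np.log(np.clip(p, 1e-300, 1))
                                   + (1 - X) * np.log(np.clip(1 - p, 1e-300, 1)))))
        if abs(ll - last_ll) < LOGLIK_RTOL * (abs(last_ll) + 1):
            last_ll = ll
            break
        last_ll = ll
    else:  # pragma: no cover
        raise RuntimeError(f"joint ML did not converge after {MAX_ITER} iterations "
                           f"(last log-likelihood {last_ll:.6f})")
    p = expit(theta[:, None] - b[None, :]) * M
    w = (p * (1 - p)).sum(axis=0)
    se = 1.0 / np.sqrt(np.maximum(w, 1e-12))
    return b, se, last_ll, it + 1


def estimate_item_difficulties(data: ResponseMatrix,
                               method: str = "conditional_ml") -> ItemBank:
    """Calibrate item difficulties from a binary response matrix.

    ``method`` is ``"conditional_ml"`` (default; conditions on raw scores,
    invariant to the person distribution and consistent with the published
    calibrations) or ``"joint_ml"`` (alternating person/item Newton steps).
    Difficulties are mean-centered after either method. Missing responses
    are skipped, never imputed; persons with extreme raw scores carry no
    information about item parameters.
    """
    if data.n_items < 2:
        raise ValueError("need at least 2 items to calibrate")
    _check_item_variance(data)
    if method == "conditional_ml":
        b, se, ll, nit = _cml_fit(data)
    elif method == "joint_ml":
        b, se, ll, nit = _jml_fit(data)
    else:
        raise ValueError(f"unknown method {method!r}")
    b = b - b.mean()
    return ItemBank(
        item_ids=list(data.items),
        difficulty=b,
        difficulty_se=se,
        normalized=True,
        meta={"method": method, "log_likelihood": ll, "n_iter": nit,
              "n_persons": data.n_persons,
              "item_observations": data.item_observation_counts().tolist()},
    )
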
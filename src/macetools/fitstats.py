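"""Item-fit diagnostics and the Andersen likelihood-ratio test.

Infit/outfit mean squares gauge how well each item conforms to the Rasch
model: outfit is the unweighted mean of squared standardized residuals
(sensitive to unexpected responses far from a person's level), infit the
information-weighted version (sensitive near the person's level). Both
have expectation ~1 under the model; values >= 1.3 indicate misfit and
>= 1.5 are unacceptable, while low values (< 0.7) indicate overfit or
redundancy and are tolerable.

The Andersen LR test is the global model/DIF check: conditional ML fits
in person subgroups are compared to the pooled fit, 2 * (sum of group
log-likelihoods - pooled log-likelihood) ~ chi2 with (G-1)(k-1) df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .rasch import (
    ItemBank,
    ResponseMatrix,
    _pattern_groups,
    conditional_log_likelihood,
    estimate_item_difficulties,
    icc_probability,
    theta_by_raw_score,
)

__all__ = [
    "ItemFit",
    "AndersenResult",
    "RaschCalibration",
    "item_fit",
    "flag_items",
    "andersen_lr_test",
    "median_split",
    "calibrate",
]

W_CLAMP = 1e-10  # floor for Bernoulli variance in residual standardization

MSQ_UPPER = 1.3
MSQ_HARD_UPPER = 1.5
MSQ_LOWER = 0.7


@dataclass
class ItemFit:
    item_id: object
    outfit_msq: float
    infit_msq: float
    n_observed: int


@dataclass
class AndersenResult:
    lr_statistic: float
    df: int
    p_value: float
    partition_label: str
    group_sizes: dict = field(default_factory=dict)


@dataclass
class RaschCalibration:
    """Bundle of a full calibration: bank, person table, fits, Andersen."""

    bank: ItemBank
    person_estimates: dict  # raw score -> PersonEstimate
    fits: list
    andersen: AndersenResult | None = None


def item_fit(data: ResponseMatrix, bank: ItemBank, thetas=None) -> list[ItemFit]:
    """Infit/outfit mean squares per item.

    ``thetas`` are per-person logits; by default the pooled-calibration ML
    estimates at each person's raw score (raw-score sufficiency makes this
    the canonical choice). Persons with extreme raw scores are excluded
    from the fit sums (their responses are fully determined by the score).
    """
    order = [bank.item_ids.index(i) if i in bank.item_ids else None
             for i in data.items]
    if any(o is None for o in order):
        raise ValueError("data items not covered by the bank")
    b = bank.difficulty[np.asarray(order)]

    mask = data.observed_mask()
    r = data.raw_scores()
    k_obs = data.observed_counts()
    nonextreme = (r > 0) & (r < k_obs)
    if not nonextreme.any():
        raise ValueError("all persons have extreme raw scores; no fit information")

    if thetas is None:
        by_score = theta_by_raw_score(bank)
        thetas = np.array([by_score[int(ri)].theta if ne else np.nan
                           for ri, ne in zip(r, nonextreme)])
    else:
        thetas = np.asarray(thetas, dtype=float)
        if not np.all(np.isfinite(thetas[nonextreme])):
            raise ValueError("thetas must be finite for non-extreme persons")

    use = nonextreme
    P = icc_probability(thetas[use, None], b[None, :])
    W = np.clip(P * (1.0 - P), W_CLAMP, None)
    X = np.where(mask[use], data.values[use], 0.0)
    Z2 = np.where(mask[use], (X - P) ** 2 / W, 0.0)
    Wm = np.where(mask[use], W, 0.0)

    fits = []
    for j, item in enumerate(data.items):
        n_obs = int(mask[use, j].sum())
        if n_obs == 0:
            fits.append(ItemFit(item, np.nan, np.nan, 0))
            continue
        outfit = float(Z2[:, j].sum() / n_obs)
        infit = float((Wm[:, j] * Z2[:, j]).sum() / Wm[:, j].sum())
        fits.append(ItemFit(item, outfit, infit, n_obs))
    return fits


def flag_items(fits: list[ItemFit], upper: float = MSQ_UPPER,
               hard_upper: float = MSQ_HARD_UPPER,
               lower: float = MSQ_LOWER) -> dict:
    """Classify each item as acceptable / overfit / misfit / unacceptable.

    Misfit (noise) is flagged on max(infit, outfit) >= ``upper`` and
    becomes unacceptable at ``hard_upper``; overfit (redundancy) on
    min < ``lower`` with max below ``upper`` — flagged but retainable,
    since low mean squares do not threaten validity.
    """
    if not fits:
        raise ValueError("empty fit list")
    out = {}
    for f in fits:
        hi = max(f.infit_msq, f.outfit_msq)
        lo = min(f.infit_msq, f.outfit_msq)
        if hi >= hard_upper:
            out[f.item_id] = "unacceptable"
        elif hi >= upper:
            out[f.item_id] = "misfit"
        elif lo < lower:
            out[f.item_id] = "overfit"
        else:
            out[f.item_id] = "acceptable"
    return out


def median_split(values, label: str = "median split") -> np.ndarray:
    """Two-group partition at the median; ties go to the lower group."""
    v = np.asarray(values, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("partition covariate contains missing values")
    med = float(np.median(v))
    return np.where(v <= med, 0, 1)


def _group_cond_ll(data: ResponseMatrix) -> float:
    bank = estimate_item_difficulties(data, method="conditional_ml")
    groups = _pattern_groups(data)
    return conditional_log_likelihood(bank.difficulty, groups)


def andersen_lr_test(data: ResponseMatrix, partition) -> AndersenResult:
    """Andersen's conditional likelihood-ratio test over a person partition.

    ``partition`` is a per-person label array (e.g. from ``median_split``
    on age). Persons with extreme raw scores contribute nothing to the
    conditional likelihoods. A group in which some item is constant
    cannot be calibrated and raises an error naming group and item.
    """
    labels = np.asarray(partition)
    if labels.shape[0] != data.n_persons:
        raise ValueError("partition length does not match number of persons")
    uniq = [u for u in dict.fromkeys(labels.tolist())]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    ll_groups = 0.0
    sizes = {}
    for g in uniq:
        sub = data.drop_persons(labels == g)
        sizes[g] = sub.n_persons
        try:
            ll_groups += _group_cond_ll(sub)
        except ValueError as e:
            raise ValueError(f"group {g!r}: {e}") from e
    ll_pooled = _group_cond_ll(data)

    lr = 2.0 * (ll_groups - ll_pooled)
    lr = max(lr, 0.0)  # clip numerical negatives
    df = (len(uniq) - 1) * (data.n_items - 1)
    p = float(chi2.sf(lr, df))
    return AndersenResult(float(lr), df, p,
                          partition_label=f"{len(uniq)} groups", group_sizes=sizes)


def calibrate(data: ResponseMatrix, method: str = "conditional_ml",
              partition=None) -> RaschCalibration:
    """Full calibration: difficulties, person table, item fits, Andersen."""
    bank = estimate_item_difficulties(data, method=method)
    persons = theta_by_raw_score(bank)
    fits = item_fit(data, bank)
    andersen = andersen_lr_test(data, partition) if partition is not None else None
    return RaschCalibration(bank, persons, fits, andersen)
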
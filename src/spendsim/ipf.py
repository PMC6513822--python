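"""Iterative proportional fitting of survey weights to zone constraints.

The weight array has one row per survey individual and one column per zone.
Starting from unit weights (no geographical restriction: any individual may
serve any zone), each sweep visits the constraint variables in a declared
order and, for every zone, multiplies the weights of each category's
members by target/simulated for that category.  Immediately after a
variable's update its simulated marginal matches the target exactly; at the
fixed point all variables' marginals match simultaneously, to within a
total-absolute-error (TAE) tolerance.

Most variables categorise an individual once (a 1-D integer code vector);
income is zone-specific — the same wage falls in different brackets under
different zones' boundaries — so its codes form an individuals x zones
matrix.  Per-zone category relabelling from missing-data harmonisation is
expressed the same way.

The child model is a single-constraint special case with a closed form:
after one sweep the weight of child i in zone z is
``target[z, cat(i)] / n_microdata[cat(i)]``, and iterating changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ORDER = [
    "age_sex",
    "household_type",
    "ethnicity",
    "student",
    "unemployment",
    "income",
]


@dataclass
class ConstraintSpec:
    """One variable of the IPF system, microdata side + target side.

    ``codes`` is either shape (n,) — one category per individual — or
    (n, n_zones) when categorisation is zone-specific.  ``targets`` is a
    zones x categories array; NaN rows mark the variable unavailable for
    that zone (no update is applied there).
    """

    name: str
    codes: np.ndarray
    n_categories: int
    targets: np.ndarray
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.codes.min() < 0 or self.codes.max() >= self.n_categories:
            raise ValueError(f"{self.name}: category codes out of range")
        if self.targets.shape[1] != self.n_categories:
            raise ValueError(f"{self.name}: target width != n_categories")

    @property
    def zone_specific(self) -> bool:
        return self.codes.ndim == 2


@dataclass
class WeightMatrix:
    """Nonnegative fractional weights, individuals x zones."""

    values: np.ndarray
    individual_ids: pd.Index
    zone_codes: pd.Index

    def to_frame(self) -> pd.DataFrame:
        """Long three-column form (individual_id, zone_code, weight)."""
        n, z = self.values.shape
        return pd.DataFrame(
            {
                "individual_id": np.repeat(self.individual_ids, z),
                "zone_code": np.tile(self.zone_codes, n),
                "weight": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeightMatrix":
        wide = df.pivot(index="individual_id", columns="zone_code", values="weight")
        return cls(wide.to_numpy(), wide.index, wide.columns)

    def zone_totals(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=0), index=self.zone_codes)


@dataclass
class FitDiagnostics:
    """Convergence record of one IPF run."""

    iterations: int
    converged: bool
    tae_history: pd.DataFrame  # sweep x variable, total TAE over zones
    final_zone_relative_error: pd.Series  # per zone, max over variables
    dropped_cells: list[tuple[str, str, str]] = field(default_factory=list)


def marginals_for(
    weights: np.ndarray, spec: ConstraintSpec
) -> np.ndarray:
    """Simulated zone x category marginal counts under ``weights``.

    counts[z, k] = sum of weights[i, z] over individuals i in category k
    (category membership per zone when codes are zone-specific).
    """
    n, n_zones = weights.shape
    out = np.zeros((n_zones, spec.n_categories))
    if spec.zone_specific:
        for z in range(n_zones):
            out[z] = np.bincount(
                spec.codes[:, z], weights=weights[:, z], minlength=spec.n_categories
            )
    else:
        for k in range(spec.n_categories):
            mask = spec.codes == k
            if mask.any():
                out[:, k] = weights[mask].sum(axis=0)
    return out


def simulated_marginals(
    weights: WeightMatrix, spec: ConstraintSpec
) -> pd.DataFrame:
    """Frame-valued wrapper of :func:`marginals_for`."""
    counts = marginals_for(weights.values, spec)
    cols = spec.categories or list(range(spec.n_categories))
    return pd.DataFrame(counts, index=weights.zone_codes, columns=cols)


def _microdata_mass(spec: ConstraintSpec, n_zones: int) -> np.ndarray:
    """Unweighted microdata count per (zone, category)."""
    if spec.zone_specific:
        out = np.zeros((n_zones, spec.n_categories))
        for z in range(n_zones):
            out[z] = np.bincount(spec.codes[:, z], minlength=spec.n_categories)
        return out
    counts = np.bincount(spec.codes, minlength=spec.n_categories)
    return np.tile(counts, (n_zones, 1)).astype(float)


def resolve_empty_cells(
    specs: list[ConstraintSpec],
    baseline: np.ndarray,
    mode: str = "drop",
    zone_codes: pd.Index | None = None,
) -> list[tuple[str, str, str]]:
    """Handle categories with positive target but zero microdata mass.

    In ``drop`` mode the offending category is removed from that zone's
    target and the remaining categories rescaled to the baseline, with a
    logged warning; ``strict`` mode raises.  Targets are modified in place.
    """
    n_zones = len(baseline)
    dropped: list[tuple[str, str, str]] = []
    for spec in specs:
        mass = _microdata_mass(spec, n_zones)
        empty = (spec.targets > 0) & (mass == 0)
        if not empty.any():
            continue
        zs, ks = np.nonzero(empty)
        cells = [
            (
                spec.name,
                str(zone_codes[z]) if zone_codes is not None else str(z),
                spec.categories[k] if spec.categories else str(k),
            )
            for z, k in zip(zs, ks)
        ]
        if mode == "strict":
            raise ValueError(f"empty cells (positive target, no microdata): {cells}")
        spec.targets[empty] = 0.0
        for z in np.unique(zs):
            row = spec.targets[z]
            total = np.nansum(row)
            if total > 0:
                spec.targets[z] = row * baseline[z] / total
        dropped.extend(cells)
        logger.warning(
            "%s: dropped %d empty cell(s) and rescaled targets", spec.name, len(cells)
        )
    return dropped


def ipf_fit(
    specs: list[ConstraintSpec],
    baseline: pd.Series,
    individual_ids: pd.Index,
    *,
    max_iter: int = 50,
    tol: float = 1e-4,
    order: list[str] | None = None,
    empty_cell: str = "drop",
) -> tuple[WeightMatrix, FitDiagnostics]:
    """Fit the weight matrix to all constraints by IPF.

    Convergence: stop once the maximum over variables and zones of
    TAE(zone)/baseline(zone) falls below ``tol``, or after ``max_iter``
    sweeps (returned with ``converged=False``).
    """
    zone_codes = baseline.index
    base = baseline.to_numpy(dtype=float)
    if (base <= 0).any():
        raise ValueError("baseline must be strictly positive per zone")
    n, n_zones = len(individual_ids), len(base)

    by_name = {s.name: s for s in specs}
    names = [v for v in (order or DEFAULT_ORDER) if v in by_name]
    names += [s.name for s in specs if s.name not in names]
    specs = [by_name[v] for v in names]

    dropped = resolve_empty_cells(specs, base, empty_cell, zone_codes)

    weights = np.ones((n, n_zones))
    history: list[dict[str, float]] = []
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        for spec in specs:
            _update(weights, spec)
        errs, zone_rel = _sweep_errors(weights, specs, base)
        history.append(errs)
        if zone_rel.max(initial=0.0) < tol:
            converged = True
            break
    if not converged:
        logger.warning("IPF did not converge in %d sweeps", max_iter)

    tae = pd.DataFrame(history)
    tae.index = pd.RangeIndex(1, len(history) + 1, name="sweep")
    diag = FitDiagnostics(
        iterations=sweeps,
        converged=converged,
        tae_history=tae,
        final_zone_relative_error=pd.Series(zone_rel, index=zone_codes),
        dropped_cells=dropped,
    )
    return WeightMatrix(weights, pd.Index(individual_ids), zone_codes), diag


def _update(weights: np.ndarray, spec: ConstraintSpec) -> None:
    """Multiplicative update for one variable: after this call the
    simulated marginal of ``spec`` equals its target wherever the target
    is available."""
    sim = marginals_for(weights, spec)
    ratio = np.ones_like(sim)
    ok = sim > 0
    ratio[ok] = spec.targets[ok] / sim[ok]
    ratio[np.isnan(spec.targets)] = 1.0  # variable unavailable for zone
    if spec.zone_specific:
        n_zones = weights.shape[1]
        for z in range(n_zones):
            weights[:, z] *= ratio[z, spec.codes[:, z]]
    else:
        weights *= ratio[:, spec.codes].T


def _sweep_errors(
    weights: np.ndarray, specs: list[ConstraintSpec], base: np.ndarray
) -> tuple[dict[str, float], np.ndarray]:
    """Post-sweep TAE per variable and per-zone relative error."""
    zone_rel = np.zeros(len(base))
    totals: dict[str, float] = {}
    for spec in specs:
        sim = marginals_for(weights, spec)
        diff = np.abs(sim - spec.targets)
        diff[np.isnan(spec.targets)] = 0.0
        per_zone = diff.sum(axis=1)
        totals[spec.name] = float(per_zone.sum())
        zone_rel = np.maximum(zone_rel, per_zone / base)
    return totals, zone_rel


def fit_child_model(
    child_codes: np.ndarray,
    child_targets: pd.DataFrame,
    individual_ids: pd.Index,
) -> WeightMatrix:
    """Closed-form single-constraint fit for the child (under-16) model.

    With one constraint the IPF fixed point is reached in one sweep:
    weight[i, z] = target[z, cat(i)] / n_microdata[cat(i)].  A category
    with positive target but no child microdata is an error.
    """
    codes = np.asarray(child_codes)
    targets = child_targets.to_numpy(dtype=float)
    n_cat = targets.shape[1]
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    starved = (counts == 0) & (targets > 0).any(axis=0)
    if starved.any():
        bad = [child_targets.columns[k] for k in np.flatnonzero(starved)]
        raise ValueError(f"child categories with target but no microdata: {bad}")
    per_cat = np.zeros((targets.shape[0], n_cat))
    ok = counts > 0
    per_cat[:, ok] = targets[:, ok] / counts[ok]
    weights = per_cat[:, codes].T
    return WeightMatrix(weights, pd.Index(individual_ids), child_targets.index)
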
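"""Internal and external validation of the microsimulation.

Internal validation asks whether the reweighting reproduced what it was
told: for each zone, the Pearson correlation between the concatenated
constraint target counts and the corresponding simulated marginals.  A
well-behaved fit yields correlations indistinguishable from 1; values
below ~0.99 flag empty cells or mis-specified constraints.

External validation asks whether the estimates agree with reality the
model never saw: (a) zone estimates aggregated to regions are compared
with survey-side regional means within +/-1.96 standard errors, and (b)
zone estimates for deprivation-linked commodities are rank-correlated
(Spearman) against an external deprivation ranking, where only the sign
pattern is meaningful (food positive, tobacco negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ipf import ConstraintSpec, WeightMatrix, marginals_for


@dataclass
class ValidationReport:
    internal: pd.Series  # per-zone Pearson r
    internal_by_constraint: pd.DataFrame  # zone x variable
    regional: pd.DataFrame | None = None
    rank_tests: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Validation report", "-----------------"]
        r = self.internal.dropna()
        if len(r):
            lines.append(
                f"internal correlation: min {r.min():.6f}, "
                f"median {r.median():.6f}, zones {len(r)}"
            )
        if self.regional is not None:
            frac = self.regional["within_95ci"].mean()
            lines.append(
                f"regional comparison: {frac:.1%} of cells within 1.96 SE"
            )
        if self.rank_tests is not None:
            for _, row in self.rank_tests.iterrows():
                lines.append(
                    f"rank correlation [{row['label']}]: rho={row['rho']:+.3f} "
                    f"p={row['p_value']:.2g} (n={int(row['n'])})"
                )
        return "\n".join(lines)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, NaN when either vector has zero variance (undefined,
    deliberately not reported as 1)."""
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def internal_validation(
    weights: WeightMatrix, specs: list[ConstraintSpec]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-zone correlation between constraint targets and simulated
    marginals, concatenated over all available constraints in declared
    order; per-constraint correlations are returned alongside for
    debugging."""
    zones = weights.zone_codes
    sims = {s.name: marginals_for(weights.values, s) for s in specs}
    overall = []
    per_var = {}
    for zi, zone in enumerate(zones):
        tcat, scat = [], []
        for s in specs:
            t = s.targets[zi]
            ok = ~np.isnan(t)
            if not ok.any():
                continue
            tcat.append(t[ok])
            scat.append(sims[s.name][zi][ok])
        overall.append(
            _pearson(np.concatenate(tcat), np.concatenate(scat))
            if tcat
            else np.nan
        )
    for s in specs:
        col = []
        for zi in range(len(zones)):
            t = s.targets[zi]
            ok = ~np.isnan(t)
            col.append(_pearson(t[ok], sims[s.name][zi][ok]) if ok.any() else np.nan)
        per_var[s.name] = col
    return (
        pd.Series(overall, index=zones, name="internal_r"),
        pd.DataFrame(per_var, index=zones),
    )


def regional_comparison(
    estimates: pd.DataFrame,
    zone_populations: pd.Series,
    region_of_zone: pd.Series,
    survey_stats: pd.DataFrame,
) -> pd.DataFrame:
    """Compare population-weighted regional means of the zone estimates
    with survey-side means, flagging agreement within 1.96 standard errors.

    ``survey_stats`` columns: region, coicop, mean, se.  Output adds
    simulated_mean and within_95ci.
    """
    pops = zone_populations.reindex(estimates.index)
    regions = region_of_zone.reindex(estimates.index)
    sim_rows = []
    for region, zones in estimates.groupby(regions).groups.items():
        w = pops.loc[zones]
        sim = estimates.loc[zones].mul(w, axis=0).sum() / w.sum()
        for code, val in sim.items():
            sim_rows.append(
                {"region": region, "coicop": code, "simulated_mean": val}
            )
    sim_df = pd.DataFrame(sim_rows)
    out = survey_stats.merge(sim_df, on=["region", "coicop"], how="inner")
    if out.empty:
        raise KeyError("no overlap between survey regions and estimated zones")
    out["within_95ci"] = (
        (out["simulated_mean"] - out["mean"]).abs() <= 1.96 * out["se"]
    )
    return out


def rank_correlation(
    estimates: pd.Series, external_rank: pd.Series
) -> tuple[float, float, int]:
    """Spearman rank correlation between a zone estimate vector and an
    external zone ranking (average ranks on ties, two-sided p via the t
    approximation).  Returns (rho, p, n over the common zones)."""
    joined = pd.concat(
        [estimates.rename("est"), external_rank.rename("rank")], axis=1
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 zones with both values")
    if joined["est"].nunique() == 1 or joined["rank"].nunique() == 1:
        raise ValueError("rank correlation undefined for all-tied input")
    rho, p = stats.spearmanr(joined["est"], joined["rank"])
    return float(rho), float(p), n


def rank_tests_table(
    external_rank: pd.Series,
    aggregates: dict[str, pd.Series],
) -> pd.DataFrame:
    """Run :func:`rank_correlation` for several labelled estimate vectors
    (typically commodity aggregates) against one external ranking."""
    rows = []
    for label, vec in aggregates.items():
        rho, p, n = rank_correlation(vec, external_rank)
        rows.append({"label": label, "rho": rho, "p_value": p, "n": n})
    return pd.DataFrame(rows)
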
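"""Sequential (Type I) sum-of-squares variance partitioning.

A general linear model is fitted term by term in a fixed order — taxonomy
(class, then species), environment, taxonomy x environment interactions,
then two spatial grid factors (90-m and 40-m cells).  Each term's SS is the
drop in residual SS when the term joins the model containing its
predecessors, so the %SS values are additive and partition the total
corrected SS exactly.  Non-significant terms can be removed backwards
(weakest first, respecting marginality); class and species are always kept.

The fit is computed by block Gram–Schmidt orthogonalisation with SVD rank
detection, so terms aliased with their predecessors contribute 0 df / 0 SS
and are flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import TRAITS

TAXONOMY_TERMS = ("tree_class", "species")
DEFAULT_ENV_ORDER = ("soil_type", "soil_rocks", "soil_depth", "PAR",
                     "aspect", "elevation", "slope", "curvature", "herbs",
                     "understory")
DEFAULT_INTERACTIONS = (("tree_class", "PAR"), ("tree_class", "elevation"),
                        ("species", "PAR"), ("species", "elevation"))
CATEGORIES = ("taxonomy", "environment", "interaction", "spatial")


@dataclass(frozen=True)
class Term:
    """One model term: a main effect or an interaction of data columns."""

    name: str
    variables: tuple          # data columns involved
    category: str             # taxonomy | environment | interaction | spatial
    removable: bool = True

    @staticmethod
    def main(column, category, removable=True):
        return Term(column, (column,), category, removable)

    @staticmethod
    def interaction(a, b):
        return Term(f"{a}:{b}", (a, b), "interaction")


@dataclass
class DesignSpec:
    """Ordered model specification for one response trait."""

    response: str
    terms: list = field(default_factory=list)
    elimination_alpha: float = 0.05

    def validate(self):
        names = [t.name for t in self.terms]
        if "tree_class" in names and "species" in names:
            if names.index("tree_class") > names.index("species"):
                raise ValueError("class must precede species")
        if "G90" in names and "G40" in names:
            if names.index("G90") > names.index("G40"):
                raise ValueError("G90 must precede G40")
        for i, t in enumerate(self.terms):
            if len(t.variables) > 1:
                for v in t.variables:
                    if v in names and names.index(v) > i:
                        raise ValueError(
                            f"main effect {v} must precede {t.name}")
        return self


def default_design(response: str,
                   env_order=DEFAULT_ENV_ORDER,
                   interactions=DEFAULT_INTERACTIONS,
                   grids=("G90", "G40"),
                   elimination_alpha: float = 0.05) -> DesignSpec:
    """The standard fitting order: taxonomy, environment, interactions, grids."""
    terms = [Term.main("tree_class", "taxonomy", removable=False),
             Term.main("species", "taxonomy", removable=False)]
    terms += [Term.main(c, "environment") for c in env_order]
    terms += [Term.interaction(a, b) for a, b in interactions]
    terms += [Term.main(g, "spatial") for g in grids]
    return DesignSpec(response, terms, elimination_alpha).validate()


def grid_factor(x, y, cell_size: float, origin=(0.0, 0.0)) -> np.ndarray:
    """Spatial grid cell labels for crown centroids."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    gx = np.floor((np.asarray(x, dtype=float) - origin[0]) / cell_size)
    gy = np.floor((np.asarray(y, dtype=float) - origin[1]) / cell_size)
    return np.array([f"{int(a)}_{int(b)}" for a, b in zip(gx, gy)])


def build_analysis_frame(crowns, trait_table: pd.DataFrame,
                         grid_origin=(0.0, 0.0)) -> pd.DataFrame:
    """Crown-level modelling frame: traits + taxonomy + env + grid factors."""
    rows = []
    for c in crowns:
        row = {"crown_id": c.crown_id, "species": c.species,
               "tree_class": c.tree_class,
               "x": c.polygon.centroid.x, "y": c.polygon.centroid.y}
        row.update({k: v for k, v in c.env.items() if k != "n_env_pixels"})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("crown_id")
    df["G90"] = grid_factor(df["x"], df["y"], 90.0, grid_origin)
    df["G40"] = grid_factor(df["x"], df["y"], 40.0, grid_origin)
    return df.join(trait_table[list(TRAITS)])


# ----------------------------------------------------------------- fitting

def _is_factor(series: pd.Series) -> bool:
    return (series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == bool)


def _term_block(data: pd.DataFrame, term: Term) -> np.ndarray:
    """Design-matrix block for one term (full indicators for factors)."""
    cols = []
    factor_parts = [v for v in term.variables if _is_factor(data[v])]
    numeric_parts = [v for v in term.variables if not _is_factor(data[v])]
    if factor_parts:
        combined = data[factor_parts[0]].astype(str)
        for v in factor_parts[1:]:
            combined = combined + "||" + data[v].astype(str)
        block = pd.get_dummies(combined, dtype=float).to_numpy()
    else:
        block = np.ones((len(data), 1))
    for v in numeric_parts:
        block = block * data[v].to_numpy(dtype=float)[:, None]
    cols.append(block)
    return np.hstack(cols)


class TraitVarianceModel:
    """Sequential-SS general linear model for one response trait.

    Parameters
    ----------
    data : DataFrame with the response column and every column named by the
        design's terms.  Rows with a missing response are dropped (count kept
        on the results).
    design : DesignSpec (see :func:`default_design`).
    """

    def __init__(self, data: pd.DataFrame, design: DesignSpec):
        design.validate()
        needed = {design.response}
        for t in design.terms:
            needed.update(t.variables)
        missing = needed - set(data.columns)
        if missing:
            raise KeyError(f"data lacks columns {sorted(missing)}")
        resp = data[design.response]
        keep = resp.notna()
        pred_cols = sorted(needed - {design.response})
        keep &= data[pred_cols].notna().all(axis=1)
        self.data = data.loc[keep]
        self.n_dropped = int((~keep).sum())
        self.design = design

    @classmethod
    def from_scene(cls, scene, response: str, design: DesignSpec | None = None,
                   trait_table: pd.DataFrame | None = None):
        """Convenience constructor from a synthetic scene (truth or retrieved)."""
        table = scene.truth if trait_table is None else trait_table
        frame = build_analysis_frame(scene.crowns, table)
        return cls(frame, design or default_design(response))

    def fit(self, eliminate: bool = False) -> "VariancePartitionResults":
        """Fit; with ``eliminate=True`` run backward elimination first."""
        if not eliminate:
            return self._fit(self.design)
        design = self.design
        while True:
            res = self._fit(design)
            cand = self._removable(design, res)
            if not cand:
                return res
            worst = max(cand, key=lambda t: res.table.loc[t.name, "p"])
            design = replace(design,
                             terms=[t for t in design.terms if t is not worst])

    def _removable(self, design, res):
        out = []
        for t in design.terms:
            if not t.removable:
                continue
            # marginality: keep main effects whose interaction is present
            blocked = any(set(t.variables) < set(o.variables)
                          for o in design.terms if o is not t)
            if blocked:
                continue
            p = res.table.loc[t.name, "p"]
            if np.isnan(p) or p > design.elimination_alpha:
                out.append(t)
        return out

    def _fit(self, design: DesignSpec) -> "VariancePartitionResults":
        data = self.data
        y = data[design.response].to_numpy(dtype=float)
        n = y.size
        if n < 3:
            raise ValueError("need at least 3 complete cases")
        ybar = y.mean()
        total_ss = float(((y - ybar) ** 2).sum())
        Q = np.ones((n, 1)) / np.sqrt(n)     # intercept
        rows = []
        for term in design.terms:
            B = _term_block(data, term)
            norms = np.linalg.norm(B, axis=0)
            B = B[:, norms > 0] / norms[norms > 0]
            R = B - Q @ (Q.T @ B)
            R = R - Q @ (Q.T @ R)            # re-orthogonalise
            if R.size:
                U, S, _ = np.linalg.svd(R, full_matrices=False)
                tol = max(R.shape) * np.finfo(float).eps * (S[0] if S.size else 0)
                rank = int((S > max(tol, 1e-10)).sum())
            else:
                rank = 0
            if rank == 0:
                rows.append((term, 0, 0.0, True))
                continue
            Qt = U[:, :rank]
            ss = float(((Qt.T @ y) ** 2).sum())
            Q = np.hstack([Q, Qt])
            rows.append((term, rank, ss, False))
        model_ss = sum(r[2] for r in rows)
        model_df = sum(r[1] for r in rows)
        resid_df = n - 1 - model_df
        resid_ss = max(total_ss - model_ss, 0.0)
        ms_resid = resid_ss / resid_df if resid_df > 0 else np.nan
        table_rows = []
        for term, df, ss, aliased in rows:
            if df > 0 and resid_df > 0 and ms_resid > 0:
                F = (ss / df) / ms_resid
                p = float(stats.f.sf(F, df, resid_df))
            else:
                F, p = np.nan, np.nan
            table_rows.append({"term": term.name, "category": term.category,
                               "df": df, "ss": ss,
                               "pct_ss": 100.0 * ss / total_ss if total_ss else np.nan,
                               "F": F, "p": p, "aliased": aliased})
        table_rows.append({"term": "Residual", "category": "residual",
                           "df": resid_df, "ss": resid_ss,
                           "pct_ss": 100.0 * resid_ss / total_ss if total_ss else np.nan,
                           "F": np.nan, "p": np.nan, "aliased": False})
        table = pd.DataFrame(table_rows).set_index("term")
        return VariancePartitionResults(design, table, n, self.n_dropped,
                                        total_ss)


@dataclass
class VariancePartitionResults:
    """ANOVA table with additive %SS plus the Fig-7-style aggregation."""

    design: DesignSpec
    table: pd.DataFrame
    n_obs: int
    n_dropped: int
    total_ss: float

    def aggregate(self) -> pd.Series:
        """%SS summed into taxonomy/environment/interaction/spatial/residual."""
        shares = self.table.groupby("category")["pct_ss"].sum()
        return shares.reindex(list(CATEGORIES) + ["residual"],
                              fill_value=0.0)

    def summary(self) -> str:
        lines = [f"Sequential ANOVA: {self.design.response} "
                 f"(n={self.n_obs}, dropped={self.n_dropped})",
                 self.table.to_string(
                     float_format=lambda v: f"{v:.4g}"),
                 "", "Aggregated %SS:"]
        agg = self.aggregate()
        lines += [f"  {k:<12s} {v:6.2f}" for k, v in agg.items()]
        return "\n".join(lines)


def expected_recovered_shares(true_shares: pd.Series,
                              results: "VariancePartitionResults") -> pd.Series:
    """Expected aggregated %SS of a fit, given the generative shares.

    A fitted model mechanically absorbs i.i.d. residual variation into every
    fitted degree of freedom: each of the ``df`` dimensions of a term span
    captures residual SS with expectation ``sigma_r^2``, so the expected
    fitted share of category k is ``true_k + df_k * resid_share/(n-1)`` and
    the expected residual share shrinks by the model df.  Comparing a fit
    against this expectation (rather than the raw generative shares) removes
    the O(df/n) bias that is a property of least squares, not of the data.
    """
    n = results.n_obs
    resid_pct = float(true_shares["residual"])
    ms = resid_pct / (n - 1)
    df_by_cat = results.table.groupby("category")["df"].sum()
    out = {}
    for cat in CATEGORIES:
        out[cat] = (float(true_shares.get(cat, 0.0))
                    + float(df_by_cat.get(cat, 0)) * ms)
    out["residual"] = float(df_by_cat.get("residual", 0)) * ms
    return pd.Series(out)


def multivariate_partition(data: pd.DataFrame,
                           design_template: DesignSpec | None = None,
                           traits=TRAITS) -> pd.DataFrame:
    """Multi-trait partition: unit-variance standardised SS summed over traits.

    Each trait is standardised to unit variance, fitted with the shared term
    order, and the per-term SS are summed; %SS is taken relative to the
    summed total.  This is a documented surrogate for a MANOVA variance
    share: it weights every trait equally and keeps additivity.
    """
    complete = data.dropna(subset=list(traits))
    tables = []
    for t in traits:
        d = complete.copy()
        sd = d[t].std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {t} is constant")
        d[t] = d[t] / sd
        design = (default_design(t) if design_template is None
                  else replace(design_template, response=t))
        tables.append(TraitVarianceModel(d, design).fit().table)
    out = tables[0][["category", "df"]].copy()
    out["ss"] = sum(tb["ss"] for tb in tables)
    total = out["ss"].sum()
    out["pct_ss"] = 100.0 * out["ss"] / total
    return out
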
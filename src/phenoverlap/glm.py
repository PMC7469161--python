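"""Binomial-logit models of parasitism with Type-II LR tests and backward elimination.

Two responses are modelled: whether a nest is parasitized at all
(nest level, Bernoulli per nest) and, for parasitized nests, the number
of larvae parasitized out of the larvae collected (larva level, binomial
per nest).  Model formulas are lists of *terms*; a term is either a main
effect (``"host"``, ``"week_c"``), a quadratic term (``"week_c^2"``) or a
two-way interaction (``"host:region"``).  Quadratic and interaction terms
impose marginality: a linear term is never tested or removed while its
square is retained, nor a main effect while one of its interactions is.

Continuous covariates entering quadratics (sampling week, overlap) are
centered when frames are built; coefficients are reported on the centered
scale and the frame records the centering constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .errors import AliasingError, ContractError, EmptySelectionError
from .field_data import NATIVE_HOSTS, NestRecord
from .phenology import OccurrenceWindow, OverlapResult

INSTAR_CLASSES = ("1-2", "3", "4", "5")
INSTAR_POOLING = {1: "1-2", 2: "1-2", 3: "3", 4: "4", 5: "5"}

#: Initial (full) model for the probability that a nest is parasitized.
DEFAULT_NEST_TERMS = (
    "host", "region", "year", "instar_class",
    "week_c", "week_c^2", "oph_c", "oph_c^2", "nest_density",
    "host:region", "host:year", "host:instar_class", "host:nest_density",
    "region:year",
)
#: Initial (full) model for the proportion of larvae parasitized per nest.
DEFAULT_LARVA_TERMS = DEFAULT_NEST_TERMS


def term_factors(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def term_order(term: str) -> int:
    """1 for a main effect, 2 for an interaction or quadratic term."""
    if ":" in term or term.endswith("^2"):
        return 2
    return 1


def contains(parent: str, child: str) -> bool:
    """True when marginality forbids removing ``child`` while ``parent`` stays.

    An interaction contains each of its main effects; a quadratic term
    contains its linear term.
    """
    if parent == child:
        return False
    if parent.endswith("^2"):
        return child == parent[:-2]
    pf = term_factors(parent)
    return len(pf) > 1 and child in pf


@dataclass
class ModelFrame:
    """Aggregated response counts plus covariates, ready for fitting.

    Attributes
    ----------
    df : DataFrame
        One row per nest with ``successes``, ``trials`` and covariate
        columns.
    level : str
        ``"nest"`` or ``"larva"``.
    categoricals : mapping
        Covariate name -> ordered level tuple (first level is reference).
    centers : mapping
        Centering constants applied to continuous covariates.
    """

    df: pd.DataFrame
    level: str
    categoricals: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    centers: Mapping[str, float] = field(default_factory=dict)

    @property
    def endog(self) -> np.ndarray:
        s = self.df["successes"].to_numpy(dtype=float)
        t = self.df["trials"].to_numpy(dtype=float)
        return np.column_stack([s, t - s])


def _encode_factor(df: pd.DataFrame, var: str, categoricals: Mapping) -> pd.DataFrame:
    if var.endswith("^2"):
        base = var[:-2]
        return pd.DataFrame({var: df[base].to_numpy(dtype=float) ** 2}, index=df.index)
    if var in categoricals:
        levels = list(categoricals[var])
        cols = {}
        for lev in levels[1:]:
            cols[f"{var}[{lev}]"] = (df[var] == lev).astype(float)
        return pd.DataFrame(cols, index=df.index)
    return pd.DataFrame({var: df[var].to_numpy(dtype=float)}, index=df.index)


def design_matrix(
    frame: ModelFrame,
    terms: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the design matrix (intercept first) and the term -> columns map."""
    df = frame.df
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    term_cols: dict[str, list[str]] = {}
    for term in terms:
        factors = term_factors(term)
        enc = _encode_factor(df, factors[0], frame.categoricals)
        for extra in factors[1:]:
            enc2 = _encode_factor(df, extra, frame.categoricals)
            prod = {}
            for c1 in enc.columns:
                for c2 in enc2.columns:
                    prod[f"{c1}:{c2}"] = enc[c1] * enc2[c2]
            enc = pd.DataFrame(prod, index=df.index)
        term_cols[term] = list(enc.columns)
        X = pd.concat([X, enc], axis=1)
    return X, term_cols


@dataclass
class ModelFit:
    """A fitted binomial-logit model.

    ``table`` has one row per design column with columns
    ``coef, se, z, p``.  ``separation`` flags fits whose coefficients
    diverged (quasi-complete separation); their p-values are unreliable.
    """

    terms: tuple[str, ...]
    table: pd.DataFrame
    llf: float
    deviance: float
    null_deviance: float
    converged: bool
    separation: bool
    n_obs: int
    endog: np.ndarray
    term_cols: Mapping[str, list[str]]
    formula: str = ""

    @property
    def pseudo_r2(self) -> float:
        """Deviance-based pseudo-R²: 1 - D_model / D_null."""
        if self.null_deviance == 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    def coef(self, column: str) -> float:
        return float(self.table.loc[column, "coef"])


def fit_binomial_logit(frame: ModelFrame, terms: Sequence[str]) -> ModelFit:
    """Fit a binomial GLM with logit link by maximum likelihood (IRLS).

    Raises
    ------
    AliasingError
        If the design matrix is rank deficient; the error names the
        aliased columns (found by pivoted QR).
    EmptySelectionError
        If the frame has no rows.
    """
    if len(frame.df) == 0:
        raise EmptySelectionError("cannot fit on an empty model frame")
    X, term_cols = design_matrix(frame, terms)
    # an identically-zero column carries no information: drop it and report
    # its term with zero df (mirrors treating its coefficient as absent);
    # genuine collinearity between informative columns stays a hard error
    zero_cols = [c for c in X.columns if c != "Intercept" and not X[c].any()]
    if zero_cols:
        X = X.drop(columns=zero_cols)
        term_cols = {t: [c for c in cols if c not in zero_cols]
                     for t, cols in term_cols.items()}
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        _, _, piv = scipy.linalg.qr(Xv, mode="economic", pivoting=True)
        aliased = [X.columns[i] for i in sorted(piv[rank:])]
        raise AliasingError(aliased)
    model = sm.GLM(frame.endog, Xv, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    separation = bool(np.abs(res.params).max() > 15.0)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        },
        index=X.columns,
    )
    return ModelFit(
        terms=tuple(terms),
        table=table,
        llf=float(res.llf),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        converged=bool(res.converged),
        separation=separation,
        n_obs=len(frame.df),
        endog=frame.endog,
        term_cols=term_cols,
        formula="successes/trials ~ " + " + ".join(terms),
    )


def dispersion_statistic(fit: ModelFit) -> float:
    """Residual deviance / residual df; >1 suggests over-dispersion."""
    resid_df = fit.n_obs - len(fit.table)
    return fit.deviance / resid_df if resid_df > 0 else float("nan")


def _lr_test(frame: ModelFrame, with_terms: list[str], without_terms: list[str],
             df_diff: int) -> tuple[float, float]:
    if df_diff == 0:
        return 0.0, 1.0  # term contributed no informative columns
    full = fit_binomial_logit(frame, with_terms)
    reduced = fit_binomial_logit(frame, without_terms)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(scipy.stats.chi2.sf(lr, df_diff))
    return lr, p


def type2_lr_anova(fit: ModelFit, frame: ModelFrame) -> pd.DataFrame:
    """Type-II likelihood-ratio ANOVA table for every term of a fit.

    Each term is tested by the LR between the model containing it and the
    model without it, in both cases excluding any higher-order term that
    contains it (marginality).  Columns: ``term, lr_chisq, df, p``.
    """
    rows = []
    for term in fit.terms:
        with_terms = [t for t in fit.terms if t == term or not contains(t, term)]
        without_terms = [t for t in with_terms if t != term]
        df_diff = len(fit.term_cols[term])
        lr, p = _lr_test(frame, with_terms, without_terms, df_diff)
        rows.append({"term": term, "lr_chisq": lr, "df": df_diff, "p": p})
    return pd.DataFrame(rows)


@dataclass
class EliminationResult:
    """Final fit plus the logged elimination path."""

    fit: ModelFit
    path: list[dict]

    @property
    def terms(self) -> tuple[str, ...]:
        return self.fit.terms


def backward_eliminate(
    frame: ModelFrame,
    full_terms: Sequence[str],
    alpha: float = 0.05,
) -> EliminationResult:
    """Backward elimination by Type-II likelihood-ratio tests.

    At each step only *removable* terms are considered: those not
    contained in any retained higher-order term.  The removable term with
    the largest p-value above ``alpha`` is dropped; ties are broken by
    dropping the higher-order term first, then lexicographically.  Stops
    when every removable term has p <= alpha.
    """
    current = list(full_terms)
    path: list[dict] = []
    while current:
        removable = [
            t for t in current
            if not any(contains(other, t) for other in current)
        ]
        tested = []
        for term in removable:
            without = [t for t in current if t != term]
            Xt, tc = design_matrix(frame, [term])
            df_diff = sum(1 for c in tc[term] if Xt[c].any())
            lr, p = _lr_test(frame, current, without, df_diff)
            tested.append({"term": term, "lr_chisq": lr, "df": df_diff, "p": p})
        droppable = [row for row in tested if row["p"] > alpha]
        if not droppable:
            path.append({"step": len(path), "dropped": None, "tested": tested})
            break
        drop = sorted(
            droppable,
            key=lambda r: (-r["p"], -term_order(r["term"]), r["term"]),
        )[0]
        current.remove(drop["term"])
        path.append({"step": len(path), "dropped": drop["term"],
                     "p": drop["p"], "tested": tested})
    return EliminationResult(fit=fit_binomial_logit(frame, current), path=path)


def deviance_explained_gain(base: ModelFit, augmented: ModelFit) -> float:
    """Increase in deviance-based pseudo-R² from ``base`` to ``augmented``.

    Both fits must share the same response vector and the base terms must
    be a subset of the augmented terms (nested models).
    """
    if not set(base.terms) <= set(augmented.terms):
        raise ContractError("models are not nested: base terms must be a subset")
    if base.endog.shape != augmented.endog.shape or not np.array_equal(base.endog, augmented.endog):
        raise ContractError("models were fitted to different responses")
    return augmented.pseudo_r2 - base.pseudo_r2


def build_frames(
    records: Sequence[NestRecord],
    overlaps: Sequence[OverlapResult],
    windows: Mapping[tuple, OccurrenceWindow],
    landcover: pd.DataFrame | None = None,
    scope: str = "region_year",
    include_unoccupied_sites: bool = False,
) -> tuple[ModelFrame, ModelFrame]:
    """Assemble nest-level and larva-level model frames.

    Nests qualify when sampled within the parasitoid occurrence window of
    their scope (region-year by default) and, unless
    ``include_unoccupied_sites`` is set, at a site-year where the
    parasitoid was observed.  Only the two main host species enter the
    frames.  The larva-level frame keeps parasitized nests only, with
    (n_parasitized, n_larvae) as the binomial response.

    ``landcover`` may carry per-nest covariates (column ``nest_id`` plus
    metric columns) merged onto both frames.
    """
    occupied = {
        (r.site_id, r.year)
        for r in records if r.n_parasitized > 0
    }
    oph_map = {(o.site_id, o.year, o.host): o.oph for o in overlaps}
    density: dict[tuple[str, int, int], int] = {}
    for r in records:
        if r.host in NATIVE_HOSTS:
            key = (r.site_id, r.year, r.week)
            density[key] = density.get(key, 0) + 1

    rows = []
    for r in records:
        if r.host not in NATIVE_HOSTS:
            continue
        wkey = (r.region, r.year) if scope == "region_year" else (r.site_id, r.year)
        window = windows.get(wkey)
        if window is None or r.week not in window:
            continue
        site_occupied = (r.site_id, r.year) in occupied
        if not include_unoccupied_sites and not site_occupied:
            continue
        oph = oph_map.get((r.site_id, r.year, r.host))
        if oph is None and not site_occupied:
            # absence rows: the parasitoid never occurred at this site-year,
            # so its phenological overlap with the host is zero by definition
            oph = 0.0
        rows.append({
            "nest_id": r.nest_id,
            "site_id": r.site_id,
            "host": r.host,
            "region": r.region,
            "year": str(r.year),
            "instar_class": INSTAR_POOLING[r.instar],
            "week": float(r.week),
            "oph": np.nan if oph is None else oph,
            "nest_density": float(density[(r.site_id, r.year, r.week)]),
            "n_larvae": r.n_larvae,
            "n_parasitized": r.n_parasitized,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise EmptySelectionError("no nests qualify after window/site filtering")
    df = df.dropna(subset=["oph"]).reset_index(drop=True)
    if df.empty:
        raise EmptySelectionError("no nests with a defined overlap value remain")
    if landcover is not None:
        df = df.merge(landcover, on="nest_id", how="left")

    centers = {"week": float(df["week"].mean()), "oph": float(df["oph"].mean())}
    df["week_c"] = df["week"] - centers["week"]
    df["oph_c"] = df["oph"] - centers["oph"]

    categoricals = {
        # alphabetical order puts A_io first, so the reported host contrast is
        # the A. urticae log-odds relative to A. io
        "host": tuple(sorted(set(df["host"]))),
        "region": tuple(sorted(set(df["region"]))),
        "year": tuple(sorted(set(df["year"]))),
        "instar_class": tuple(c for c in INSTAR_CLASSES if c in set(df["instar_class"])),
    }

    nest_df = df.copy()
    nest_df["successes"] = (nest_df["n_parasitized"] > 0).astype(int)
    nest_df["trials"] = 1
    nest_frame = ModelFrame(nest_df, "nest", categoricals, centers)

    larva_df = df[df["n_parasitized"] > 0].reset_index(drop=True).copy()
    if larva_df.empty:
        raise EmptySelectionError("no parasitized nests for the larva-level frame")
    larva_df["successes"] = larva_df["n_parasitized"]
    larva_df["trials"] = larva_df["n_larvae"]
    larva_cats = {
        k: tuple(lv for lv in v if lv in set(larva_df[k])) for k, v in categoricals.items()
    }
    larva_frame = ModelFrame(larva_df, "larva", larva_cats, centers)
    return nest_frame, larva_frame
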
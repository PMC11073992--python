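"""Dyadic mixed-effects inference for Anna Karenina and consensus models.

An Anna Karenina model regresses pairwise similarity on the pair-mean of
an individual trait (here loneliness): a negative slope means high
scorers are dissimilar both to each other and to low scorers.  Because
every participant appears in many pairs and the similarity measure is
symmetric, each unordered pair is entered twice with member roles swapped
("doubling"), the model carries crossed random intercepts for the first
pair member, the second pair member and the target, and the Satterthwaite
degrees of freedom are halved to undo the doubled sample size, with the p
value recomputed from the t distribution at the halved df.

All variables are z-scored on the analysis sample before fitting, so the
reported slopes are standardized coefficients.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import fit_crossed_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "LMMFit",
    "build_doubled_dyads",
    "fit_mixed_model",
    "tail_adjust",
    "consensus_moderation",
    "compare_target_distributions",
    "median_split_targets",
    "AnnaKareninaModel",
]

TAILS = ("one_negative", "one_positive", "two")


@dataclass
class ModelSpec:
    """Specification of one dyadic (or participant-level) mixed model."""

    outcome: str
    fixed: list[str]
    random_intercepts: tuple[str, ...] = ("participant1", "participant2", "target")
    doubled: bool = True
    tail: str = "one_negative"

    def __post_init__(self):
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.doubled and not {"participant1", "participant2"} <= set(
                self.random_intercepts):
            raise ValueError("doubled fits require random intercepts for "
                             "both pair members")


@dataclass
class EffectRow:
    name: str
    beta: float
    se: float
    t: float
    df_sat: float
    df_adj: float
    p_two: float
    p_one: float | None
    ci_low: float
    ci_high: float


@dataclass
class LMMFit:
    """Tidy fixed-effect table plus fit diagnostics."""

    effects: list[EffectRow]
    spec: ModelSpec
    re_var: dict[str, float]
    sigma2: float
    n_obs: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> EffectRow:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])

    def to_dict(self) -> dict:
        return {
            "effects": [vars(e) for e in self.effects],
            "spec": {**vars(self.spec),
                     "random_intercepts": list(self.spec.random_intercepts)},
            "re_var": self.re_var, "sigma2": self.sigma2,
            "n_obs": self.n_obs, "converged": self.converged,
            "notes": self.notes,
        }


def build_doubled_dyads(dyads: pd.DataFrame) -> pd.DataFrame:
    """Enter each unordered pair twice with the member roles swapped."""
    ordered = list(zip(dyads["participant1"], dyads["participant2"],
                       dyads["target"]))
    seen = set()
    for p1, p2, t in ordered:
        key = (p1, p2, t)
        rev = (p2, p1, t)
        if rev in seen or key in seen:
            raise ValueError("input already contains doubled/duplicate pairs")
        seen.add(key)
    swapped = dyads.copy()
    swapped["participant1"] = dyads["participant2"].values
    swapped["participant2"] = dyads["participant1"].values
    return pd.concat([dyads, swapped], ignore_index=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def tail_adjust(p_two: float, t: float, tail: str) -> float | None:
    """One-tailed p from a two-tailed p and the estimate's sign."""
    if tail == "two":
        return None
    right = tail == "one_positive"
    matches = (t > 0) if right else (t < 0)
    if t == 0:
        return 0.5
    return p_two / 2.0 if matches else 1.0 - p_two / 2.0


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> LMMFit:
    """REML fit of a dyad-table mixed model with the doubling adjustment.

    Rows flagged undefined (``flag_undefined``) or with missing values in
    the outcome/predictors are excluded with a logged count.  When the
    requested random-effect structure fails to fit, the target intercept is
    dropped first and the model refit (logged in the fit's notes).
    """
    cols = [spec.outcome] + list(spec.fixed)
    work = data.copy()
    n0 = len(work)
    if "flag_undefined" in work.columns:
        work = work[~work["flag_undefined"].astype(bool)]
    work = work.dropna(subset=cols)
    dropped = n0 - len(work)
    if dropped:
        logger.warning("%d rows excluded from the model fit", dropped)

    y = _zscore(work[spec.outcome].values.astype(float))
    X = np.column_stack(
        [np.ones(len(work))]
        + [_zscore(work[c].values.astype(float)) for c in spec.fixed])
    fe_names = ["(Intercept)"] + list(spec.fixed)

    notes = [f"{dropped} rows excluded"] if dropped else []
    structures = [list(spec.random_intercepts)]
    if "target" in spec.random_intercepts and len(spec.random_intercepts) > 1:
        structures.append([g for g in spec.random_intercepts if g != "target"])

    res = None
    for structure in structures:
        groups = {g: work[g].values for g in structure}
        try:
            res = fit_crossed_lmm(y, X, groups, fe_names)
        except Exception as err:  # singular/failed fit: reduce and retry
            notes.append(f"random structure {structure} failed ({err}); reduced")
            continue
        if res.converged:
            if structure != list(spec.random_intercepts):
                notes.append(f"random structure reduced to {structure}")
            break
    if res is None:
        raise RuntimeError("mixed-model fit failed for all random structures")
    notes.extend(res.notes)

    effects = []
    for k, name in enumerate(fe_names):
        beta, se, df = res.params[k], res.se[k], res.df_sat[k]
        # Doubling adjustment: each unordered pair enters the fit twice, so
        # the naive fit sees twice the information actually present.  The
        # adjustment removes it on both axes: the Satterthwaite df is halved
        # and the squared standard error doubled, so the reported p value
        # matches the information content of the undoubled data.  (Halving
        # the df alone leaves the t statistic inflated by sqrt(2); verified
        # by null simulation.)
        if spec.doubled:
            se = se * np.sqrt(2.0)
            df_adj = df / 2.0
        else:
            df_adj = df
        tval = beta / se if se > 0 else 0.0
        p_two = float(2.0 * stats.t.sf(abs(tval), df_adj))
        p_one = tail_adjust(p_two, tval, spec.tail)
        tcrit = stats.t.ppf(0.975, df_adj)
        effects.append(EffectRow(
            name=name, beta=float(beta), se=float(se), t=float(tval),
            df_sat=float(df), df_adj=float(df_adj), p_two=p_two,
            p_one=p_one, ci_low=float(beta - tcrit * se),
            ci_high=float(beta + tcrit * se)))
    return LMMFit(effects=effects, spec=spec, re_var=res.re_var,
                  sigma2=res.sigma2, n_obs=res.n_obs,
                  converged=res.converged, notes=notes)


def consensus_moderation(dyads: pd.DataFrame, coding,
                         predictor: str = "mean_loneliness",
                         outcome: str = "similarity",
                         doubled: bool = True,
                         tail: str = "two") -> LMMFit:
    """Loneliness x consensus interaction model.

    ``coding`` is either a mapping from target id to a consensus code
    (e.g. +1 high / -1 low) or a mapping to each target's continuous
    consensus value (its mean pairwise similarity).  The model includes
    both main effects and their product; the interaction row is named
    ``"<predictor>:consensus"``.
    """
    work = dyads.copy()
    missing = set(work["target"]) - set(coding)
    if missing:
        raise ValueError(f"targets missing from the consensus coding: {missing}")
    work["consensus"] = work["target"].map(coding).astype(float)
    zc = _zscore(work["consensus"].values)
    zp = _zscore(work[predictor].values.astype(float))
    work["_interaction"] = zp * zc
    work = work.rename(columns={"_interaction": f"{predictor}:consensus"})
    spec = ModelSpec(outcome=outcome,
                     fixed=[predictor, "consensus", f"{predictor}:consensus"],
                     doubled=doubled, tail=tail)
    return fit_mixed_model(work, spec)


def compare_target_distributions(dyads: pd.DataFrame,
                                 outcome: str = "similarity",
                                 doubled: bool = True) -> pd.DataFrame:
    """Pairwise target comparisons of the similarity distributions.

    For every pair of targets, fits a doubled-dyad model of similarity on
    a target indicator with participant random intercepts; returns a tidy
    table of betas, t, df and two-tailed p values.
    """
    targets = sorted(pd.unique(dyads["target"]))
    if len(targets) < 2:
        raise ValueError("need at least two targets to compare")
    rows = []
    for ta, tb in itertools.combinations(targets, 2):
        sub = dyads[dyads["target"].isin([ta, tb])].copy()
        sub["target_code"] = (sub["target"] == tb).astype(float)
        spec = ModelSpec(outcome=outcome, fixed=["target_code"],
                         random_intercepts=("participant1", "participant2"),
                         doubled=doubled, tail="two")
        fit = fit_mixed_model(sub, spec)
        eff = fit.effect("target_code")
        rows.append((ta, tb, eff.beta, eff.se, eff.t, eff.df_adj, eff.p_two))
    return pd.DataFrame(rows, columns=["target_a", "target_b", "beta", "se",
                                       "t", "df", "p_two"])


def median_split_targets(dyads: pd.DataFrame,
                         outcome: str = "similarity") -> dict[str, str]:
    """Split targets into high/low consensus by mean pairwise similarity.

    Targets at or above the median go high.  Even target counts give an
    exact half split; with an odd count the median target is assigned high
    (logged).  Equal means tie-break by target label order (logged).
    """
    means = dyads.groupby("target")[outcome].mean()
    if len(means) < 2:
        raise ValueError("need at least two targets")
    frame = means.reset_index().sort_values(
        [outcome, "target"], ascending=[False, True], kind="mergesort")
    if frame[outcome].duplicated(keep=False).any():
        logger.info("tied consensus means broken by target label order")
    ordered = frame.set_index("target")[outcome]
    n = len(ordered)
    n_high = n // 2 + (n % 2)
    if n % 2:
        logger.info("odd target count: median target assigned high")
    labels = {}
    for k, t in enumerate(ordered.index):
        labels[t] = "high" if k < n_high else "low"
    return labels


class AnnaKareninaModel(BaseEstimator):
    """Dyadic Anna Karenina mixed model as a scikit-learn estimator.

    Fits pairwise similarity on the pair-mean of an individual trait with
    crossed random intercepts, doubling and df-halving.

    Parameters
    ----------
    predictor : dyad-table column holding the pair-mean trait score.
    outcome : dyad-table column holding the pairwise similarity.
    covariates : extra fixed-effect columns.
    doubled : double the table before fitting (expects undoubled input).
    tail : 'one_negative' (idiosyncrasy hypothesis), 'one_positive' or 'two'.
    random_target_intercept : include a target random intercept.

    Attributes
    ----------
    fit_ : the full :class:`LMMFit`.
    beta_, se_, t_, df_, p_one_, p_two_ : headline statistics for the
        predictor's standardized fixed effect.
    """

    def __init__(self, predictor="mean_loneliness", outcome="similarity",
                 covariates=(), doubled=True, tail="one_negative",
                 random_target_intercept=True):
        self.predictor = predictor
        self.outcome = outcome
        self.covariates = covariates
        self.doubled = doubled
        self.tail = tail
        self.random_target_intercept = random_target_intercept

    def fit(self, dyads: pd.DataFrame, y=None):
        work = build_doubled_dyads(dyads) if self.doubled else dyads
        ri = ["participant1", "participant2"]
        if self.random_target_intercept:
            ri.append("target")
        spec = ModelSpec(outcome=self.outcome,
                         fixed=[self.predictor, *self.covariates],
                         random_intercepts=tuple(ri),
                         doubled=self.doubled, tail=self.tail)
        self.fit_ = fit_mixed_model(work, spec)
        eff = self.fit_.effect(self.predictor)
        self.beta_ = eff.beta
        self.se_ = eff.se
        self.t_ = eff.t
        self.df_ = eff.df_adj
        self.p_two_ = eff.p_two
        self.p_one_ = eff.p_one
        return self


class ConsensusSimilarityModel(BaseEstimator):
    """Participant-level model of similarity-to-consensus on a trait.

    One observation per participant x target; random intercept for the
    participant (a target intercept is attempted first and dropped if the
    fit degenerates, mirroring the reduced structure used when the fuller
    model overfits).
    """

    def __init__(self, predictor="loneliness", outcome="similarity",
                 covariates=(), tail="one_negative",
                 random_target_intercept=False):
        self.predictor = predictor
        self.outcome = outcome
        self.covariates = covariates
        self.tail = tail
        self.random_target_intercept = random_target_intercept

    def fit(self, table: pd.DataFrame, y=None):
        ri = ["participant"]
        if self.random_target_intercept:
            ri.append("target")
        spec = ModelSpec(outcome=self.outcome,
                         fixed=[self.predictor, *self.covariates],
                         random_intercepts=tuple(ri), doubled=False,
                         tail=self.tail)
        self.fit_ = fit_mixed_model(table, spec)
        eff = self.fit_.effect(self.predictor)
        self.beta_ = eff.beta
        self.se_ = eff.se
        self.t_ = eff.t
        self.df_ = eff.df_adj
        self.p_two_ = eff.p_two
        self.p_one_ = eff.p_one
        return self
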
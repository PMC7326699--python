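"""Gene-signature scoring and the study's comparator risk models.

Covers four model families benchmarked against each other:

* baseline clinical (age and/or ISS Cox model);
* generic signature scorers (mean-difference or weighted-sum over a supplied
  gene list — published signature gene lists are user-supplied files);
* signature extended with clinical covariates;
* the parsimonious four-feature Cox model (age, ISS, PHF19, MMSET expression).

Each model exposes ``fit(train_cohorts)`` and ``predict(cohort) -> Series`` of
continuous risk scores (higher = higher risk), which is the interface the
challenge evaluation consumes.  Expression features are standardized within
each cohort before pooling, so microarray-like and RNA-seq-like cohorts can be
mixed coherently; patient ranking within a cohort is unaffected by this by
construction.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import FittedRiskModel, fit_cox
from .errors import DegenerateFeatureError, UndefinedMetricError
from .simulate import Cohort

__all__ = [
    "SignatureDefinition",
    "score_signature",
    "extend_with_clinical",
    "build_four_feature_model",
    "dichotomize_scores",
    "BaselineClinicalModel",
    "SignatureRiskModel",
    "FourFeatureCoxModel",
    "RandomScoreModel",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureDefinition:
    """A gene signature: up/down gene sets, optional weights, scoring rule."""

    name: str
    up_genes: list[str]
    down_genes: list[str]
    weights: dict[str, float] | None = None
    rule: str = "mean_difference"

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"signature {self.name!r}: genes in both up and "
                             f"down sets: {sorted(overlap)[:5]}")
        if self.rule not in ("mean_difference", "weighted_sum"):
            raise ValueError(f"unknown signature rule {self.rule!r}")
        if self.rule == "weighted_sum":
            if self.weights is None:
                raise ValueError("weighted_sum rule requires weights")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)


def score_signature(cohort: Cohort, signature: SignatureDefinition) -> pd.Series:
    """Per-patient signature score on one cohort.

    mean_difference: mean(up-gene expression) - mean(down-gene expression)
    over the genes present; weighted_sum: sum of weight * expression.  Genes
    absent from the cohort are dropped with a logged warning.
    """
    present = [g for g in signature.genes if g in cohort.expression.index]
    dropped = len(signature.genes) - len(present)
    if dropped:
        logger.warning(
            "signature %s: %d of %d genes absent from cohort %s; dropped",
            signature.name, dropped, len(signature.genes), cohort.cohort_id,
        )
    if not present:
        raise UndefinedMetricError(
            f"signature {signature.name!r}: no genes present in cohort "
            f"{cohort.cohort_id}"
        )
    expr = cohort.expression
    if signature.rule == "weighted_sum":
        missing_w = [g for g in present if g not in signature.weights]
        if missing_w:
            raise ValueError(
                f"signature {signature.name!r}: no weight for genes "
                f"{missing_w[:5]}"
            )
        w = np.array([signature.weights[g] for g in present])
        scores = w @ expr.loc[present].to_numpy()
    else:
        up = [g for g in signature.up_genes if g in expr.index]
        down = [g for g in signature.down_genes if g in expr.index]
        scores = np.zeros(cohort.n_patients)
        if up:
            scores = scores + expr.loc[up].to_numpy().mean(axis=0)
        if down:
            scores = scores - expr.loc[down].to_numpy().mean(axis=0)
    return pd.Series(scores, index=cohort.expression.columns, name=signature.name)


def extend_with_clinical(
    signature_scores: pd.Series,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    use_age: bool = True,
    use_iss: bool = True,
    **cox_kwargs,
) -> FittedRiskModel:
    """Cox fit on (signature score [, age] [, ISS as numeric 1-3])."""
    if not np.isfinite(signature_scores.to_numpy(float)).all():
        raise ValueError("non-finite signature scores")
    feats = pd.DataFrame({"score": signature_scores})
    clin = clinical.loc[signature_scores.index]
    if use_age:
        feats["age"] = clin["age"].to_numpy(float)
    if use_iss:
        feats["iss"] = clin["iss"].to_numpy(float)
    form = "signature_only" if not (use_age or use_iss) else "cox"
    return fit_cox(feats, survival, model_form=form, **cox_kwargs)


def _standardized_gene(cohort: Cohort, gene: str) -> np.ndarray:
    row = cohort.expression.loc[gene].to_numpy(float)
    sd = row.std(ddof=0)
    if sd == 0:
        raise DegenerateFeatureError(
            f"gene {gene!r} constant in cohort {cohort.cohort_id}"
        )
    return (row - row.mean()) / sd


def _four_feature_table(
    cohorts: list[Cohort], phf19_gene: str, mmset_gene: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled (age, iss, phf19, mmset) features + PFS survival; expression
    standardized per cohort before pooling."""
    feats, survs = [], []
    for cohort in cohorts:
        for gene in (phf19_gene, mmset_gene):
            if gene not in cohort.expression.index:
                raise KeyError(
                    f"gene {gene!r} missing from cohort {cohort.cohort_id}"
                )
        feats.append(pd.DataFrame(
            {
                "age": cohort.clinical["age"].to_numpy(float),
                "iss": cohort.clinical["iss"].to_numpy(float),
                "phf19": _standardized_gene(cohort, phf19_gene),
                "mmset": _standardized_gene(cohort, mmset_gene),
            },
            index=cohort.clinical.index,
        ))
        survs.append(cohort.survival)
    return pd.concat(feats), pd.concat(survs)


def build_four_feature_model(
    train: list[Cohort],
    phf19_gene: str = "PHF19",
    mmset_gene: str = "MMSET",
    **cox_kwargs,
) -> FittedRiskModel:
    """Fit the four-feature Cox model (age, ISS, PHF19, MMSET) on pooled
    training cohorts."""
    features, survival = _four_feature_table(train, phf19_gene, mmset_gene)
    return fit_cox(features, survival, **cox_kwargs)


def dichotomize_scores(
    scores: pd.Series, survival: pd.DataFrame, threshold_months: float = 18.0
) -> pd.Series:
    """Binary high-risk calls from continuous scores at the observed prevalence.

    The top-q fraction of scores is called high-risk, where q is the prevalence
    of the high-risk label at ``threshold_months`` among evaluable patients.
    Ties at the cut are broken by patient id order.
    """
    from .evaluate import label_high_risk

    if not np.isfinite(scores.to_numpy(float)).all():
        raise ValueError("non-finite scores")
    labels, evaluable = label_high_risk(survival.loc[scores.index], threshold_months)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise UndefinedMetricError(
            f"no evaluable patients at {threshold_months} months"
        )
    q = float(labels[evaluable].sum()) / n_eval
    n_call = int(round(q * len(scores)))
    order = sorted(scores.index, key=lambda pid: (-scores.loc[pid], pid))
    calls = pd.Series(0, index=scores.index, dtype=int)
    calls.loc[order[:n_call]] = 1
    return calls


class BaselineClinicalModel:
    """Age and/or ISS Cox baseline."""

    def __init__(self, use_age: bool = True, use_iss: bool = True,
                 model_id: str = "baseline"):
        if not (use_age or use_iss):
            raise ValueError("baseline needs at least one of age, ISS")
        self.use_age = use_age
        self.use_iss = use_iss
        self.model_id = model_id
        self.fitted: FittedRiskModel | None = None

    def _features(self, cohort: Cohort) -> pd.DataFrame:
        cols = {}
        if self.use_age:
            cols["age"] = cohort.clinical["age"].to_numpy(float)
        if self.use_iss:
            cols["iss"] = cohort.clinical["iss"].to_numpy(float)
        return pd.DataFrame(cols, index=cohort.clinical.index)

    def fit(self, cohorts: list[Cohort]) -> "BaselineClinicalModel":
        feats = pd.concat([self._features(c) for c in cohorts])
        surv = pd.concat([c.survival for c in cohorts])
        self.fitted = fit_cox(feats, surv, model_form="clinical_only")
        return self

    def predict(self, cohort: Cohort) -> pd.Series:
        return self.fitted.linear_predictor(self._features(cohort))


class SignatureRiskModel:
    """A supplied gene signature, optionally extended with age/ISS via Cox."""

    def __init__(self, signature: SignatureDefinition, use_age: bool = False,
                 use_iss: bool = False, model_id: str | None = None):
        self.signature = signature
        self.use_age = use_age
        self.use_iss = use_iss
        suffix = ("+age" if use_age else "") + ("+iss" if use_iss else "")
        self.model_id = model_id or signature.name + suffix
        self.fitted: FittedRiskModel | None = None

    def fit(self, cohorts: list[Cohort]) -> "SignatureRiskModel":
        scores = pd.concat([score_signature(c, self.signature) for c in cohorts])
        clin = pd.concat([c.clinical for c in cohorts])
        surv = pd.concat([c.survival for c in cohorts])
        self.fitted = extend_with_clinical(
            scores, clin, surv, use_age=self.use_age, use_iss=self.use_iss
        )
        return self

    def predict(self, cohort: Cohort) -> pd.Series:
        feats = pd.DataFrame({"score": score_signature(cohort, self.signature)})
        if self.use_age:
            feats["age"] = cohort.clinical["age"].to_numpy(float)
        if self.use_iss:
            feats["iss"] = cohort.clinical["iss"].to_numpy(float)
        if self.fitted is None:
            # raw signature scores rank patients without any fit
            return feats["score"]
        return self.fitted.linear_predictor(feats)


class FourFeatureCoxModel:
    """The parsimonious four-feature model: age, ISS, PHF19, MMSET."""

    def __init__(self, phf19_gene: str = "PHF19", mmset_gene: str = "MMSET",
                 model_id: str = "four_feature"):
        self.phf19_gene = phf19_gene
        self.mmset_gene = mmset_gene
        self.model_id = model_id
        self.fitted: FittedRiskModel | None = None

    def fit(self, cohorts: list[Cohort]) -> "FourFeatureCoxModel":
        self.fitted = build_four_feature_model(
            cohorts, self.phf19_gene, self.mmset_gene
        )
        return self

    def predict(self, cohort: Cohort) -> pd.Series:
        feats, _ = _four_feature_table([cohort], self.phf19_gene, self.mmset_gene)
        return self.fitted.linear_predictor(feats)


class RandomScoreModel:
    """Pure-noise scores; the null competitor on any leaderboard."""

    def __init__(self, seed: int = 0, model_id: str = "noise"):
        self.seed = seed
        self.model_id = model_id

    def fit(self, cohorts: list[Cohort]) -> "RandomScoreModel":
        return self

    def predict(self, cohort: Cohort) -> pd.Series:
        # deterministic per (seed, cohort_id)
        stream = zlib.crc32(cohort.cohort_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )
        return pd.Series(rng.standard_normal(cohort.n_patients),
                         index=cohort.expression.columns)
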
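"""Inter-rater agreement over accept/reject annotations.

Implements the three statistics used to evaluate the QC workflow:
observed percent agreement (mean pairwise over all rater pairs), Cohen's
kappa for two raters (marginal-based chance correction, large-sample
confidence interval), and the Brennan–Prediger kappa for two or more
raters (uniform-chance correction, (p_o - 1/q)/(1 - 1/q), bootstrap
confidence interval). For two categories the Brennan–Prediger kappa
reduces to 2 p_o - 1.

Kappa interpretation bands: 0.41-0.60 moderate, 0.61-0.80 substantial,
0.81-1.0 almost perfect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

KAPPA_BANDS = ((0.41, 0.60, "moderate"), (0.61, 0.80, "substantial"),
               (0.81, 1.00, "almost perfect"))


def interpret_kappa(kappa: float) -> str:
    for lo, hi, label in KAPPA_BANDS:
        if lo <= kappa <= hi:
            return label
    return "poor to fair"


@dataclass
class RatingMatrix:
    """Complete trials x raters categorical rating matrix."""

    ratings: pd.DataFrame  # index: trial_id, columns: reviewer_id
    phase: str = ""

    def __post_init__(self):
        if self.ratings.isna().any().any():
            raise ValidationError("rating matrix must be listwise complete")
        if self.ratings.shape[1] < 2:
            raise ValidationError("at least two raters required")
        if self.ratings.shape[0] < 1:
            raise ValidationError("at least one trial required")

    @property
    def n_trials(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @property
    def categories(self) -> list:
        return sorted(pd.unique(self.ratings.to_numpy().ravel()).tolist())

    @classmethod
    def from_csv(cls, path, phase: str = "") -> "RatingMatrix":
        """First column trial_id, one column per rater, values accept/reject."""
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 3:
            raise SchemaError("ratings CSV needs a trial_id column and >= 2 rater columns")
        df = df.set_index(df.columns[0])
        return cls(df, phase=phase)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.ratings.rename_axis("trial_id").to_csv(path)
        return path


@dataclass(frozen=True)
class AgreementResult:
    p_o: float
    kappa: float | None
    ci_low: float | None
    ci_high: float | None
    method: str
    n_trials: int
    n_raters: int

    def __post_init__(self):
        if not 0 <= self.p_o <= 1:
            raise ValidationError("p_o must lie in [0, 1]")
        if self.kappa is not None and not -1 - 1e-12 <= self.kappa <= 1 + 1e-12:
            raise ValidationError("kappa must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = {"method": self.method, "p_o": self.p_o, "kappa": self.kappa,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "n_trials": self.n_trials, "n_raters": self.n_raters}
        if self.kappa is not None:
            d["interpretation"] = interpret_kappa(self.kappa)
        return d


def percent_agreement(m: RatingMatrix) -> float:
    """Mean over all trials and unordered rater pairs of rating equality."""
    cols = list(m.ratings.columns)
    if len(cols) < 2:
        raise ValidationError("at least two raters required")
    pair_means = [
        float((m.ratings[a].to_numpy() == m.ratings[b].to_numpy()).mean())
        for a, b in itertools.combinations(cols, 2)
    ]
    return float(np.mean(pair_means))


def cohen_kappa(m: RatingMatrix) -> AgreementResult:
    """Cohen's kappa for exactly two raters with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the rater marginals;
    SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)). When both raters are
    constant on the same category (p_e = 1) kappa is undefined and
    reported as None alongside p_o.
    """
    if m.n_raters != 2:
        raise ValidationError("Cohen's kappa requires exactly two raters")
    a = m.ratings.iloc[:, 0].to_numpy()
    b = m.ratings.iloc[:, 1].to_numpy()
    n = len(a)
    cats = m.categories
    p_o = float((a == b).mean())
    p_e = float(sum((a == c).mean() * (b == c).mean() for c in cats))
    if p_e >= 1.0 - 1e-12:
        return AgreementResult(p_o, None, None, None, "cohen", n, 2)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    lo = float(np.clip(kappa - 1.959964 * se, -1.0, 1.0))
    hi = float(np.clip(kappa + 1.959964 * se, -1.0, 1.0))
    return AgreementResult(p_o, float(kappa), lo, hi, "cohen", n, 2)


def brennan_prediger_kappa(m: RatingMatrix, q: int = 2, n_boot: int = 2000,
                           seed: int = 0) -> AgreementResult:
    """Brennan–Prediger kappa with a nonparametric bootstrap 95% CI.

    kappa_BP = (p_o - 1/q) / (1 - 1/q) where p_o is the mean pairwise
    percent agreement and q the number of rating categories. The CI
    resamples trials with replacement (percentile method, seeded).
    """
    if q < 2:
        raise ValidationError("q must be >= 2")

    def bp(df: pd.DataFrame) -> tuple[float, float]:
        cols = list(df.columns)
        arr = df.to_numpy()
        pair_means = [float((arr[:, i] == arr[:, j]).mean())
                      for i, j in itertools.combinations(range(len(cols)), 2)]
        p_o = float(np.mean(pair_means))
        return p_o, (p_o - 1.0 / q) / (1.0 - 1.0 / q)

    p_o, kappa = bp(m.ratings)
    lo = hi = None
    if n_boot > 0 and m.n_trials > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, m.n_trials, size=(n_boot, m.n_trials))
        arr = m.ratings.to_numpy()
        pairs = list(itertools.combinations(range(m.n_raters), 2))
        boots = np.empty(n_boot)
        for k in range(n_boot):
            sub = arr[idx[k]]
            po_k = np.mean([(sub[:, i] == sub[:, j]).mean() for i, j in pairs])
            boots[k] = (po_k - 1.0 / q) / (1.0 - 1.0 / q)
        lo, hi = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        lo, hi = min(lo, kappa), max(hi, kappa)
    return AgreementResult(p_o, float(kappa), lo, hi, "brennan_prediger",
                           m.n_trials, m.n_raters)


def agreement_table(m: RatingMatrix, methods: tuple[str, ...] = ("brennan_prediger",),
                    q: int = 2, seed: int = 0) -> pd.DataFrame:
    """Tidy results table (method, phase, p_o, kappa, CI) for the CLI."""
    rows = []
    for method in methods:
        if method == "cohen":
            for a, b in itertools.combinations(m.ratings.columns, 2):
                res = cohen_kappa(RatingMatrix(m.ratings[[a, b]], m.phase))
                rows.append({"method": "cohen", "raters": f"{a}/{b}",
                             "phase": m.phase, **res.to_dict()})
        elif method == "brennan_prediger":
            res = brennan_prediger_kappa(m, q=q, seed=seed)
            rows.append({"method": "brennan_prediger", "raters": "all",
                         "phase": m.phase, **res.to_dict()})
        else:
            raise ValidationError(f"unknown agreement method {method!r}")
    return pd.DataFrame(rows)[
        ["method", "raters", "phase", "p_o", "kappa", "ci_low", "ci_high",
         "n_trials", "n_raters"]]
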
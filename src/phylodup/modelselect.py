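"""Bayes-factor clock-model selection from log marginal likelihoods.

Given the estimated log marginal likelihoods of two competing models
(e.g. strict vs. relaxed clock on the same matrix), the null model H0
is the one with the *lower* marginal likelihood and the test statistic
is twice the log Bayes factor,

    2 ln BF = 2 (ln ML_alt - ln ML_H0)  >=  0,

interpreted on the Kass-Raftery evidence bands: < 2 inconclusive,
[2, 6) positive, [6, 10) strong, >= 10 very strong evidence against
H0.  Boundary values fall in the higher band.  The "positive" band is
also displayed as "Weak" to match common tabulations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Evidence",
    "ModelComparison",
    "two_log_bf",
    "classify_evidence",
    "format_bf",
    "compare_table",
    "comparisons_to_frame",
]


class Evidence(enum.Enum):
    INCONCLUSIVE = "inconclusive"
    POSITIVE = "positive"
    STRONG = "strong"
    VERY_STRONG = "very_strong"

    @property
    def display(self) -> str:
        """Tabulation-style label ('Weak' for the positive band)."""
        return {
            Evidence.INCONCLUSIVE: "Inconclusive",
            Evidence.POSITIVE: "Weak",
            Evidence.STRONG: "Strong",
            Evidence.VERY_STRONG: "Very strong",
        }[self]

    @property
    def kass_raftery(self) -> str:
        """Canonical Kass-Raftery band name."""
        return {
            Evidence.INCONCLUSIVE: "not worth more than a bare mention",
            Evidence.POSITIVE: "positive",
            Evidence.STRONG: "strong",
            Evidence.VERY_STRONG: "very strong",
        }[self]


def two_log_bf(logml_h0: float, logml_alt: float) -> float:
    """2*(ln ML_alt - ln ML_H0); exact, rounding is display-only."""
    if not (math.isfinite(logml_h0) and math.isfinite(logml_alt)):
        raise ValueError("log marginal likelihoods must be finite")
    return 2.0 * (logml_alt - logml_h0)


def classify_evidence(value: float) -> Evidence:
    """Kass-Raftery band of a (non-negative, H0-oriented) 2 ln BF."""
    if value < 0:
        raise ValueError(
            "negative 2lnBF: orient H0 to the lower marginal likelihood first"
        )
    if value < 2:
        return Evidence.INCONCLUSIVE
    if value < 6:
        return Evidence.POSITIVE
    if value < 10:
        return Evidence.STRONG
    return Evidence.VERY_STRONG


def format_bf(value: float) -> str:
    """Two decimals with the trailing zero trimmed: 5.08, 5.3, 1.0, 58.2."""
    s = f"{value:.2f}"
    if s.endswith("0") and "." in s and not s.endswith(".00"):
        s = s[:-1]
    if s.endswith(".00"):
        s = s[:-1]  # keep one decimal: '1.00' -> '1.0'
    return s


@dataclass
class ModelComparison:
    name: str
    h0_label: str
    alt_label: str
    logml_h0: float
    logml_alt: float

    def __post_init__(self):
        # auto-orient: H0 is the model with the lower marginal likelihood
        if self.logml_h0 > self.logml_alt:
            self.h0_label, self.alt_label = self.alt_label, self.h0_label
            self.logml_h0, self.logml_alt = self.logml_alt, self.logml_h0

    @property
    def two_log_bf(self) -> float:
        return two_log_bf(self.logml_h0, self.logml_alt)

    @property
    def evidence(self) -> Evidence:
        return classify_evidence(self.two_log_bf)

    def to_dict(self) -> dict:
        return {
            "matrix": self.name,
            "H0": self.h0_label,
            "selected": self.alt_label,
            "logml_H0": self.logml_h0,
            "logml_selected": self.logml_alt,
            "two_log_bf": float(self.two_log_bf),
            "two_log_bf_display": format_bf(self.two_log_bf),
            "evidence": self.evidence.display,
            "evidence_kass_raftery": self.evidence.kass_raftery,
        }


def compare_table(records) -> list[ModelComparison]:
    """Build oriented comparisons from (name, label_a, logml_a, label_b,
    logml_b) records; input order of the two models does not matter."""
    out = []
    for name, label_a, logml_a, label_b, logml_b in records:
        out.append(
            ModelComparison(
                name=name,
                h0_label=label_a,
                alt_label=label_b,
                logml_h0=float(logml_a),
                logml_alt=float(logml_b),
            )
        )
    return out


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])
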
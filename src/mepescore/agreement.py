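"""Inter-reader agreement: Cohen's kappa with CI and Landis-Koch labels.

Two readers scoring the same patients are compared feature by feature,
score value by score value, and on the final dichotomous EPE call of each
rule set.  Kappa is chance-corrected agreement, kappa = (p_o - p_e)/(1 - p_e)
with p_e from the marginal products; its CI uses the standard asymptotic
(Fleiss-type) variance, computed through statsmodels.  Multi-category score
agreement is unweighted by default, with linear weights as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .scoring import BASE_FEATURES, ScoreRuleSet, builtin_rulesets

__all__ = ["KappaResult", "cohens_kappa", "landis_koch_label", "agreement_table"]

_LANDIS_KOCH = (
    (0.00, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    """Qualitative agreement label for a kappa value (Landis-Koch ranges)."""
    if kappa < 0:
        return "poor"
    label = "slight"
    for lo, name in _LANDIS_KOCH:
        if kappa >= lo:
            label = name
    return label


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with CI, qualitative label, and raw percent agreement."""

    kappa: float
    ci: tuple[float, float]
    label: str
    percent_agreement: float
    p_observed: float
    p_expected: float
    n: int
    degenerate: bool = False


def cohens_kappa(
    ratings1: Sequence,
    ratings2: Sequence,
    ci_level: float = 0.95,
    weights: Literal["unweighted", "linear"] = "unweighted",
) -> KappaResult:
    """Chance-corrected agreement between two raters on the same items.

    The two rating vectors must be aligned item by item and share one
    category space.  Both raters constant and identical (p_e = 1) is the
    degenerate perfect-agreement case: kappa is defined as 1 and flagged.
    """
    r1 = np.asarray(ratings1)
    r2 = np.asarray(ratings2)
    if r1.size == 0 or r1.shape != r2.shape:
        raise ValueError("ratings must be equal-length and non-empty")
    cats = np.union1d(r1, r2)
    idx1 = np.searchsorted(cats, r1)
    idx2 = np.searchsorted(cats, r2)
    k = cats.size
    table = np.zeros((k, k))
    np.add.at(table, (idx1, idx2), 1)
    n = int(table.sum())
    p_o = float(np.trace(table) / n)
    marg1 = table.sum(axis=1) / n
    marg2 = table.sum(axis=0) / n
    p_e = float(np.dot(marg1, marg2))

    if k == 1:
        # both raters constant and identical: perfect but chance-saturated
        return KappaResult(
            kappa=1.0, ci=(1.0, 1.0), label="almost perfect",
            percent_agreement=1.0, p_observed=1.0, p_expected=1.0,
            n=n, degenerate=True,
        )

    from scipy import stats as _st

    wt = None if weights == "unweighted" else "linear"
    res = _sm_kappa(table, wt=wt, return_results=True)
    kappa = float(res.kappa)
    z = _st.norm.ppf(0.5 + ci_level / 2)
    half = z * float(res.std_kappa)
    lo, hi = kappa - half, kappa + half
    return KappaResult(
        kappa=kappa,
        ci=(max(-1.0, float(lo)), min(1.0, float(hi))),
        label=landis_koch_label(kappa),
        percent_agreement=p_o,
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )


def agreement_table(
    reader1: pd.DataFrame,
    reader2: pd.DataFrame,
    rulesets: Sequence[ScoreRuleSet] | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Inter-reader concordance report over features, scores and diagnoses.

    Inputs are patient-aligned cohort frames (standard columns, one row per
    patient) from the two readers.  Output rows: kappa per individual
    feature (including interface > 10 mm and measurable disease), kappa per
    rule-set score value and per positive-diagnosis call, plus overall
    percent-agreement rows for features and for diagnoses.
    """
    from .io import cohort_to_lesions  # local import to avoid a cycle

    if len(reader1) != len(reader2):
        raise ValueError("reader frames must cover the same patients")
    if "patient_id" in reader1.columns and "patient_id" in reader2.columns:
        if not np.array_equal(
            reader1["patient_id"].to_numpy(), reader2["patient_id"].to_numpy()
        ):
            raise ValueError("patient_id columns are not aligned between readers")
    if rulesets is None:
        rulesets = list(builtin_rulesets().values())

    lesions1 = cohort_to_lesions(reader1)
    lesions2 = cohort_to_lesions(reader2)

    rows: list[dict] = []

    def add(section: str, item: str, res: KappaResult) -> None:
        rows.append({
            "section": section,
            "item": item,
            "kappa": res.kappa,
            "kappa_lo": res.ci[0],
            "kappa_hi": res.ci[1],
            "label": res.label,
            "percent_agreement": res.percent_agreement,
        })

    feature_flags = list(BASE_FEATURES) + ["interface_gt10", "measurable_disease"]
    feat_agree_cells = []
    for flag in feature_flags:
        v1 = [l.flag(flag) for l in lesions1]
        v2 = [l.flag(flag) for l in lesions2]
        add("feature", flag, cohens_kappa(v1, v2, ci_level))
        feat_agree_cells.append(np.asarray(v1) == np.asarray(v2))

    diag_agree_cells = []
    for rs in rulesets:
        a1 = [rs.assign(l) for l in lesions1]
        a2 = [rs.assign(l) for l in lesions2]
        add("score", rs.name,
            cohens_kappa([a.score for a in a1], [a.score for a in a2], ci_level))
        add("diagnosis", f"{rs.name} > {rs.positivity_threshold}",
            cohens_kappa([a.positive_call for a in a1],
                         [a.positive_call for a in a2], ci_level))
        diag_agree_cells.append(
            np.asarray([a.positive_call for a in a1])
            == np.asarray([a.positive_call for a in a2])
        )

    rows.append({
        "section": "overall", "item": "features",
        "kappa": np.nan, "kappa_lo": np.nan, "kappa_hi": np.nan, "label": "",
        "percent_agreement": float(np.mean(np.column_stack(feat_agree_cells))),
    })
    rows.append({
        "section": "overall", "item": "diagnoses",
        "kappa": np.nan, "kappa_lo": np.nan, "kappa_hi": np.nan, "label": "",
        "percent_agreement": float(np.mean(np.column_stack(diag_agree_cells))),
    })
    return pd.DataFrame(rows)
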
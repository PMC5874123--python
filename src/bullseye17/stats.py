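"""Group comparison, maximum-likelihood diagnostic classification and
operator-variability analysis of the per-segment measurements.

Measurements live in a wide table: one row per subject (or per
subject/session for variability studies), one column per
(segment, parameter) pair named ``seg<k>_<parameter>``, plus a ``group``
column with two levels (e.g. ``AS`` and ``control``).

Group comparison uses Welch's unpaired two-sample t-test per segment;
operator variability uses the true paired t-test since the same subjects
are measured in every session.  The diagnostic classifier fits a univariate
Gaussian per group on one segment's parameter, assigns each subject to the
higher-likelihood class, and sweeps the log-likelihood-ratio threshold for
the ROC curve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

SEGMENTS = tuple(range(1, 18))
PARAMETERS = ("area_cm2", "max_thickness_mm", "mass_g")


def seg_col(segment: int, parameter: str) -> str:
    return f"seg{segment}_{parameter}"


def make_table(cases: list[tuple[str, pd.DataFrame]],
               subjects: list | None = None) -> pd.DataFrame:
    """Assemble a wide measurement table from per-case segment tables.

    ``cases`` is a list of (group_label, per_segment_dataframe); each
    per-segment frame has a ``segment`` column plus any of the parameter
    columns (area_cm2, max_thickness_mm, mass_g).
    """
    rows = []
    for i, (group, df) in enumerate(cases):
        rec: dict = {"group": group,
                     "subject": subjects[i] if subjects else i}
        dfi = df.set_index("segment")
        for p in PARAMETERS:
            if p not in dfi.columns:
                continue
            for s in SEGMENTS:
                if s in dfi.index:
                    rec[seg_col(s, p)] = float(dfi.loc[s, p])
        rows.append(rec)
    return pd.DataFrame(rows)


def p_tier(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "ns"


def _two_groups(table: pd.DataFrame) -> tuple[str, str]:
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    return tuple(groups)


def compare_groups(table: pd.DataFrame, parameter: str = "area_cm2"
                   ) -> pd.DataFrame:
    """Per-segment Welch two-sample comparison of one parameter.

    Returns group means, the t statistic, the two-sided p-value and its
    significance tier for every segment with data.
    """
    g1, g2 = _two_groups(table)
    a = table[table["group"] == g1]
    b = table[table["group"] == g2]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for s in SEGMENTS:
        col = seg_col(s, parameter)
        if col not in table.columns:
            continue
        xa = a[col].dropna().to_numpy()
        xb = b[col].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            continue
        with warnings.catch_warnings():
            # near-identical groups trip a scipy precision warning; the
            # t = 0 / p = 1 outcome is exactly what we want there
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        if np.isnan(t) and np.allclose(xa, xa.mean()) and np.allclose(xb, xb.mean()) \
                and np.isclose(xa.mean(), xb.mean()):
            t, p = 0.0, 1.0
        rows.append({"segment": s, f"mean_{g1}": xa.mean(), f"mean_{g2}": xb.mean(),
                     "t": float(t), "p": float(p), "tier": p_tier(float(p))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# maximum-likelihood diagnostic classification
# ---------------------------------------------------------------------------

def _gaussian_loglik(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return sps.norm.logpdf(x, loc=mu, scale=sd)


def ml_classify(table: pd.DataFrame, segment: int,
                parameter: str = "area_cm2", positive: str = "AS",
                score: str = "likelihood") -> dict:
    """Gaussian maximum-likelihood two-class test on one segment's parameter.

    A univariate Gaussian is fitted per group; each subject is assigned to
    the class with the higher likelihood.  Sensitivity is the correctly
    classified fraction of the positive (disease) group, specificity that
    of the other group, and the AUC comes from sweeping the
    log-likelihood-ratio threshold (``score="raw"`` ranks by the raw
    measurement instead).
    """
    g1, g2 = _two_groups(table)
    if positive not in (g1, g2):
        raise ValueError(f"positive class {positive!r} not among groups {g1, g2}")
    negative = g2 if positive == g1 else g1
    col = seg_col(segment, parameter)
    x = table[col].to_numpy(dtype=float)
    y = (table["group"] == positive).to_numpy()
    xp, xn = x[y], x[~y]
    if len(xp) < 2 or len(xn) < 2:
        raise ValueError("each group needs at least 2 subjects")
    mu_p, sd_p = xp.mean(), xp.std(ddof=1)
    mu_n, sd_n = xn.mean(), xn.std(ddof=1)
    for name, sd in ((positive, sd_p), (negative, sd_n)):
        if sd <= 0:
            raise ValueError(f"zero within-group variance in group {name!r}")

    llr = _gaussian_loglik(x, mu_p, sd_p) - _gaussian_loglik(x, mu_n, sd_n)
    pred_pos = llr > 0
    sensitivity = float(np.mean(pred_pos[y]))
    specificity = float(np.mean(~pred_pos[~y]))
    ranking = llr if score == "likelihood" else x
    auc = float(roc_auc_score(y.astype(int), ranking))
    return {"segment": segment, "sensitivity": sensitivity,
            "specificity": specificity, "auc": auc}


def classifier_report(table: pd.DataFrame, parameter: str = "area_cm2",
                      positive: str = "AS", score: str = "likelihood",
                      segments=None) -> pd.DataFrame:
    """Per-segment classifier metrics plus a mean +/- SD footer row."""
    segments = list(segments) if segments is not None else \
        [s for s in SEGMENTS if seg_col(s, parameter) in table.columns]
    rows = [ml_classify(table, s, parameter, positive, score) for s in segments]
    rep = pd.DataFrame(rows)
    footer = {"segment": "mean±SD"}
    for c in ("sensitivity", "specificity", "auc"):
        footer[c] = f"{rep[c].mean():.2f}±{rep[c].std(ddof=1):.2f}"
    return pd.concat([rep, pd.DataFrame([footer])], ignore_index=True)


# ---------------------------------------------------------------------------
# operator variability
# ---------------------------------------------------------------------------

def _paired_p(xa: np.ndarray, xb: np.ndarray) -> float:
    d = xa - xb
    if np.allclose(d, 0.0):
        return 1.0  # identically zero differences: no evidence of a difference
    return float(sps.ttest_rel(xa, xb).pvalue)


def operator_variability(table_a1: pd.DataFrame, table_a2: pd.DataFrame,
                         table_b1: pd.DataFrame,
                         parameter: str = "area_cm2") -> pd.DataFrame:
    """Intra-/interoperator paired comparisons of repeated measurements.

    ``table_a1``/``table_a2`` are the first and second sessions of operator
    A, ``table_b1`` the session of operator B, all on the same subjects (by
    the ``subject`` column).  Per segment the output reports mean +/- SD of
    each session and paired-t p tiers for A1 vs A2 (intraoperator) and
    A1/A2 vs B1 (interoperator).
    """
    tables = {"a1": table_a1.sort_values("subject").reset_index(drop=True),
              "a2": table_a2.sort_values("subject").reset_index(drop=True),
              "b1": table_b1.sort_values("subject").reset_index(drop=True)}
    subj = tables["a1"]["subject"].to_numpy()
    for name, t in tables.items():
        if not np.array_equal(t["subject"].to_numpy(), subj):
            raise ValueError(f"subject mismatch between sessions (table {name})")
    rows = []
    for s in SEGMENTS:
        col = seg_col(s, parameter)
        if col not in tables["a1"].columns:
            continue
        x = {k: t[col].to_numpy(dtype=float) for k, t in tables.items()}
        row = {"segment": s}
        for k in tables:
            row[f"mean_{k}"] = x[k].mean()
            row[f"sd_{k}"] = x[k].std(ddof=1)
        for name, (u, v) in {"p_intra_a1_a2": ("a1", "a2"),
                             "p_inter_a1_b1": ("a1", "b1"),
                             "p_inter_a2_b1": ("a2", "b1")}.items():
            p = _paired_p(x[u], x[v])
            row[name] = p
            row[name.replace("p_", "tier_")] = "<0.05" if p < 0.05 else "≥0.05"
        rows.append(row)
    return pd.DataFrame(rows)
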
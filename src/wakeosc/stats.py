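"""Mixed-effects models, FDR correction, overnight-change correlations and
Steiger's test for the developmental analysis layer.

The central model is

    Measure ~ Task + Time*Age + Group + Sex
              + (1|Participant) + (1|Participant:Session)

with Time coded evening=0 / morning=1, Group control=0 / ADHD=1, Sex
female=0 / male=1, Task treatment-coded against "oddball", and Age in years
(uncentered).  Estimation is by maximum likelihood; Wald t statistics use
residual degrees of freedom (rows minus fixed-effect parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectEstimate",
    "CorrelationResult",
    "SteigerResult",
    "MEASURE_COLUMNS",
    "build_table",
    "load_measure_table",
    "fit_lme",
    "per_channel_lme",
    "fdr_correct",
    "overnight_change",
    "steiger_z",
]

FACTOR_COLUMNS = ("Participant", "Session", "Task", "Time", "Age", "Group", "Sex")
MEASURE_COLUMNS = (
    "Amplitude",
    "Density",
    "Exponent",
    "Offset",
    "Power",
    "PeriodicPower",
)

_SYNONYMS = {
    "participant": "Participant",
    "session": "Session",
    "task": "Task",
    "time": "Time",
    "age": "Age",
    "group": "Group",
    "sex": "Sex",
    "amplitude": "Amplitude",
    "density": "Density",
    "exponent": "Exponent",
    "offset": "Offset",
    "power": "Power",
    "periodicpower": "PeriodicPower",
    "periodic_power": "PeriodicPower",
}


@dataclass
class EffectEstimate:
    term: str
    beta: float
    t: float
    p: float
    df: int


@dataclass
class CorrelationResult:
    measure: str
    r: float
    n: int
    p: float
    p_fdr: float = np.nan


@dataclass
class SteigerResult:
    z: float
    p: float


def build_table(fragments: list[dict]) -> pd.DataFrame:
    """Assemble one row per recording from measure fragments.

    Fragments sharing (Participant, Session, Task, Time) are merged;
    conflicting duplicate values raise.
    """
    key = ["Participant", "Session", "Task", "Time"]
    merged: dict[tuple, dict] = {}
    for frag in fragments:
        missing = [c for c in key + ["Age", "Group", "Sex"] if c not in frag]
        if missing:
            raise ValueError(f"fragment missing factors {missing}: {frag}")
        k = tuple(frag[c] for c in key)
        row = merged.setdefault(k, {})
        for col, val in frag.items():
            if col in row and row[col] != val and not (
                pd.isna(row[col]) and pd.isna(val)
            ):
                raise ValueError(
                    f"conflicting duplicate value for {col} in recording {k}"
                )
            row[col] = val
    return pd.DataFrame(list(merged.values()))


def load_measure_table(path) -> pd.DataFrame:
    """Load a measure table CSV, normalizing column names to the canonical
    schema (accepts the deposited channel-averaged table layout)."""
    table = pd.read_csv(path)
    table = table.rename(
        columns={c: _SYNONYMS.get(c.strip().lower(), c) for c in table.columns}
    )
    missing = [c for c in FACTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measure table missing factor columns {missing}")
    return table


def _code_factors(table: pd.DataFrame) -> pd.DataFrame:
    coded = table.copy()
    if coded["Time"].dtype == object:
        coded["TimeCode"] = (coded["Time"] == "morning").astype(float)
    else:
        coded["TimeCode"] = coded["Time"].astype(float)
    if "Group" in coded and coded["Group"].dtype == object:
        coded["GroupCode"] = (coded["Group"] == "ADHD").astype(float)
    elif "Group" in coded:
        coded["GroupCode"] = coded["Group"].astype(float)
    if "Sex" in coded and coded["Sex"].dtype == object:
        coded["SexCode"] = (coded["Sex"] == "male").astype(float)
    elif "Sex" in coded:
        coded["SexCode"] = coded["Sex"].astype(float)
    return coded


_TERM_LABELS = {
    "Intercept": "Intercept",
    "TimeCode": "Time",
    "GroupCode": "Group",
    "SexCode": "Sex",
    "TimeCode:Age": "Time:Age",
    "Age": "Age",
}


def _relabel(term: str) -> str:
    if term in _TERM_LABELS:
        return _TERM_LABELS[term]
    if term.startswith("C(Task"):
        level = term.split("[T.")[-1].rstrip("]")
        return f"Task[{level}]"
    return term


def fit_lme(
    table: pd.DataFrame,
    outcome: str,
    include: tuple[str, ...] = ("Task", "Time*Age", "Group", "Sex"),
) -> list[EffectEstimate]:
    """Fit the channel-averaged mixed-effects model for one outcome.

    Random intercepts for Participant and for Session nested in
    Participant; fixed effects per ``include``.  Returns one estimate per
    fixed-effect term (treatment-coded Task levels expand to one term
    each).  Singular fits are returned with a warning flag in the term name
    rather than dropped.
    """
    if table["Participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    coded = _code_factors(table).dropna(subset=[outcome])
    parts = []
    for item in include:
        if item == "Task":
            if coded["Task"].nunique() > 1:
                parts.append("C(Task, Treatment('oddball'))")
        elif item == "Time*Age":
            parts.append("TimeCode*Age")
        elif item == "Time":
            parts.append("TimeCode")
        elif item == "Group":
            parts.append("GroupCode")
        elif item == "Sex":
            parts.append("SexCode")
        else:
            parts.append(item)
    formula = f"Q('{outcome}') ~ " + " + ".join(parts)
    multi_session = coded.groupby("Participant")["Session"].nunique().max() > 1
    vc = {"Session": "0 + C(Session)"} if multi_session else None
    model = smf.mixedlm(
        formula,
        coded,
        groups=coded["Participant"],
        re_formula="1",
        vc_formula=vc,
    )
    try:
        fit = model.fit(reml=False, method=["lbfgs", "bfgs"])
        fe_params, bse = fit.fe_params, fit.bse_fe
    except np.linalg.LinAlgError:
        # singular random-effects covariance (variances at zero): report
        # the degenerate-model estimates rather than dropping the fit
        ols = smf.ols(formula, coded).fit()
        fe_params, bse = ols.params, ols.bse
    k_fixed = len(fe_params)
    df = len(coded) - k_fixed
    out = []
    for term, beta in fe_params.items():
        se = bse[term]
        t = beta / se
        p = float(2 * spstats.t.sf(abs(t), df))
        out.append(
            EffectEstimate(term=_relabel(term), beta=float(beta), t=float(t), p=p, df=df)
        )
    return out


def per_channel_lme(
    table: pd.DataFrame,
    outcome: str,
    include: tuple[str, ...] = ("Task", "Time*Age", "Group", "Sex"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit the model separately for each channel and FDR-correct per term.

    ``table`` is long-format with a ``Channel`` column.  Returns a frame
    with one row per (channel, term): beta, t, p, p_fdr, significant.
    """
    rows = []
    for channel, sub in table.groupby("Channel"):
        for est in fit_lme(sub, outcome, include):
            rows.append(
                {
                    "Channel": channel,
                    "term": est.term,
                    "beta": est.beta,
                    "t": est.t,
                    "p": est.p,
                    "df": est.df,
                }
            )
    frame = pd.DataFrame(rows)
    frame["p_fdr"] = np.nan
    frame["significant"] = False
    for term, sub in frame.groupby("term"):
        mask, p_adj = fdr_correct(sub["p"].to_numpy(), q=q)
        frame.loc[sub.index, "p_fdr"] = p_adj
        frame.loc[sub.index, "significant"] = mask
    return frame


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: reject all p(i) <= (i/m)·q up to the
    largest such i.  Returns (rejection mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return mask, p_adj


def overnight_change(
    table: pd.DataFrame,
    measures: tuple[str, ...] = MEASURE_COLUMNS,
    q: float = 0.05,
) -> tuple[pd.DataFrame, list[CorrelationResult]]:
    """Per-participant morning-minus-evening differences and their Pearson
    correlation with age, FDR-corrected across measures.

    Values are first averaged across sessions (and tasks) within each time
    point.  Participants missing a time point are excluded.  Measures whose
    differences are constant (correlation undefined) get r = NaN and are
    excluded from the FDR family.
    """
    measures = tuple(m for m in measures if m in table.columns)
    per_time = (
        table.groupby(["Participant", "Time"])[list(measures) + ["Age"]]
        .mean()
        .reset_index()
    )
    eve = per_time[per_time["Time"] == "evening"].set_index("Participant")
    mor = per_time[per_time["Time"] == "morning"].set_index("Participant")
    both = eve.index.intersection(mor.index)
    diff = pd.DataFrame(index=both)
    diff["Age"] = eve.loc[both, "Age"]
    for m in measures:
        diff[m] = mor.loc[both, m] - eve.loc[both, m]
    results = []
    for m in measures:
        x, y = diff["Age"].to_numpy(), diff[m].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
            results.append(
                CorrelationResult(measure=m, r=np.nan, n=int(ok.sum()), p=np.nan)
            )
            continue
        r, p = spstats.pearsonr(x[ok], y[ok])
        results.append(
            CorrelationResult(measure=m, r=float(r), n=int(ok.sum()), p=float(p))
        )
    defined = [res for res in results if np.isfinite(res.p)]
    if defined:
        _, p_adj = fdr_correct([res.p for res in defined], q=q)
        for res, adj in zip(defined, p_adj):
            res.p_fdr = float(adj)
    return diff.reset_index(), results


def steiger_z(r12: float, r13: float, r23: float, n: int) -> SteigerResult:
    """Steiger's Z1* test for two dependent correlations sharing variable 1.

    Compares r12 against r13, accounting for their dependence through r23.
    Antisymmetric under swapping r12 and r13; two-sided p from the normal
    distribution.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    for r in (r12, r13, r23):
        if not -1 <= r <= 1:
            raise ValueError("correlations must lie in [-1, 1]")
    det = 1 + 2 * r12 * r13 * r23 - r12**2 - r13**2 - r23**2
    if det < -1e-12:
        raise ValueError("correlation matrix is not positive semidefinite")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    s = psi / (1 - rbar**2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3) / (2 * (1 - s)))
    p = float(2 * spstats.norm.sf(abs(z)))
    return SteigerResult(z=float(z), p=p)
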
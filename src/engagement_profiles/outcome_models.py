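"""Profile characterization and mixed-model prediction of clinical outcomes.

Two questions are answered here.  First, do the engagement profiles differ
at baseline (one-way ANOVA for continuous variables, chi-square for
categorical, Tukey HSD post hoc)?  Second, do profiles predict change in
clinical outcomes from baseline to 6 months?  The latter uses a general
linear mixed model per outcome,

    value ~ group + time + group:time + sex + age + log(DUP) + (1 | user)

fitted by REML (statsmodels ``MixedLM``), with Type-III F tests whose
denominator degrees of freedom come from a Satterthwaite-type approximation
computed analytically for the random-intercept covariance structure
(statsmodels does not provide denominator df itself).  Group and time enter
with sum-to-zero (deviation) coding so the Type-III hypotheses are the
standard ones; model-implied cell means are evaluated at the analysis
sample's covariate means.

No multiple-testing correction is applied across outcomes by default —
reports carry an explicit caveat — with optional Benjamini–Hochberg
adjustment available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

MULTIPLICITY_CAVEAT = (
    "No correction for multiple comparisons was applied across outcomes; "
    "interpret nominal p-values accordingly."
)


# ---------------------------------------------------------------------------
# Design construction (sum-to-zero coding for Type-III tests)
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    groups: list[str]  # sorted group labels; last is the sum-coding drop level
    timepoints: list[int]  # [0, 6]
    colnames: list[str]
    cov_means: dict[str, float]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def rows(self, group_codes: np.ndarray, time_codes: np.ndarray,
             cov: np.ndarray) -> np.ndarray:
        """Build the fixed-effects matrix from coded factors + centered covs."""
        n = len(group_codes)
        g = self.n_groups
        X = [np.ones(n)]
        gcols = []
        for j in range(g - 1):
            col = (group_codes == j).astype(float) - (group_codes == g - 1)
            gcols.append(col)
            X.append(col)
        tcol = np.where(time_codes == 1, 1.0, -1.0)  # 6 months = +1
        X.append(tcol)
        for col in gcols:
            X.append(col * tcol)
        return np.column_stack(X + [cov[:, i] for i in range(cov.shape[1])])

    def cell_row(self, group: str, timepoint: int) -> np.ndarray:
        """Design row for one group x time cell at average covariates."""
        g = self.n_groups
        gi = self.groups.index(group)
        gcode = np.zeros(g - 1)
        if gi < g - 1:
            gcode[gi] = 1.0
        else:
            gcode[:] = -1.0
        t = 1.0 if timepoint == self.timepoints[1] else -1.0
        return np.concatenate([[1.0], gcode, [t], gcode * t, np.zeros(3)])

    def term_selector(self, term: str) -> np.ndarray:
        """L matrix selecting the coefficients of one model term."""
        g = self.n_groups
        p = len(self.colnames)
        if term == "group":
            idx = range(1, g)
        elif term == "time":
            idx = [g]
        elif term == "group:time":
            idx = range(g + 1, 2 * g)
        else:
            raise ValueError(f"unknown term {term!r}")
        L = np.zeros((len(list(idx)), p))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        return L


def _build_design(groups: list[str]) -> list[str]:
    g = len(groups)
    names = ["Intercept"]
    names += [f"group[S.{lbl}]" for lbl in groups[:-1]]
    names += ["time[S.6]"]
    names += [f"group[S.{lbl}]:time[S.6]" for lbl in groups[:-1]]
    names += ["sex_c", "age_c", "dup_log_c"]
    return names


# ---------------------------------------------------------------------------
# Satterthwaite machinery for the random-intercept model
# ---------------------------------------------------------------------------

class _SatterthwaiteEngine:
    """Denominator-df approximation for contrasts in a random-intercept LMM.

    With V = sigma2*I + tau2*Z Z' the REML information matrix of
    theta = (sigma2, tau2) and the derivative of C = (X'V^-1 X)^-1 with
    respect to theta are available in closed form; a contrast L beta then
    gets df = 2*(L C L')^2 / Var(L C L') by the delta method.  Multi-row
    contrasts use the eigencontrast-averaging construction.
    """

    def __init__(self, X: np.ndarray, user_codes: np.ndarray,
                 sigma2: float, tau2: float):
        n, p = X.shape
        Z = np.zeros((n, user_codes.max() + 1))
        Z[np.arange(n), user_codes] = 1.0
        ZZt = Z @ Z.T
        V = sigma2 * np.eye(n) + tau2 * ZZt
        Vinv = np.linalg.inv(V)
        VinvX = Vinv @ X
        self.C = np.linalg.inv(X.T @ VinvX)
        P = Vinv - VinvX @ self.C @ VinvX.T
        # REML information of (sigma2, tau2); pinv guards boundary tau2 = 0
        PV = (P, P @ ZZt)
        info = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                info[i, j] = 0.5 * np.trace(PV[i] @ PV[j])
        self.info_inv = np.linalg.pinv(info)
        # dC/dtheta_i = C X' V^-1 V_i V^-1 X C
        M1 = VinvX.T @ VinvX
        M2 = VinvX.T @ ZZt @ VinvX
        self.dC = (self.C @ M1 @ self.C, self.C @ M2 @ self.C)
        self.n_obs = n
        self.resid_df = n - p

    def df_1d(self, l: np.ndarray) -> float:
        var = float(l @ self.C @ l)
        grad = np.array([float(l @ d @ l) for d in self.dC])
        denom = float(grad @ self.info_inv @ grad)
        if denom <= 0 or var <= 0:
            return float(self.resid_df)
        return float(np.clip(2.0 * var * var / denom, 1.0, 1e7))

    def ftest(self, L: np.ndarray, beta: np.ndarray) -> tuple[float, int, float, float]:
        """Return (F, df1, df2, p) for H0: L beta = 0."""
        L = np.atleast_2d(L)
        q = L.shape[0]
        M = L @ self.C @ L.T
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
        if q == 1:
            df2 = self.df_1d(L[0])
        else:
            # eigencontrasts of the contrast covariance, df averaged as in
            # the standard multi-df Satterthwaite construction
            vals, vecs = np.linalg.eigh(M)
            keep = vals > vals.max() * 1e-10
            nus = []
            for lam, u in zip(vals[keep], vecs[:, keep].T):
                nus.append(self.df_1d(u @ L))
            nus = np.asarray(nus)
            ok = nus > 2.0
            if not ok.any():
                df2 = float(self.resid_df)
            else:
                E = float((nus[ok] / (nus[ok] - 2.0)).sum())
                df2 = 2.0 * E / (E - q) if E > q else float(self.resid_df)
        p = float(stats.f.sf(F, q, df2))
        return F, q, df2, p


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    f_stat: float
    df1: int
    df2: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "se": self.se,
            "F": self.f_stat,
            "df": [self.df1, round(self.df2, 1)],
            "p": self.p_value,
        }


@dataclass
class MixedModelResult:
    """Fitted group x time mixed model for one outcome."""

    outcome_name: str
    groups: list[str]
    params: pd.Series
    se: pd.Series
    sigma2: float
    tau2: float
    f_tests: dict[str, ContrastResult]
    cell_means: pd.DataFrame
    n_obs: int
    n_users: int
    n_dropped: int
    converged: bool
    singular: bool
    design: _Design = field(repr=False, default=None)
    engine: _SatterthwaiteEngine = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "groups": self.groups,
            "n_obs": self.n_obs,
            "n_users": self.n_users,
            "n_dropped": self.n_dropped,
            "converged": self.converged,
            "singular": self.singular,
            "sigma2": self.sigma2,
            "tau2": self.tau2,
            "fixed_effects": {
                k: {"estimate": float(v), "se": float(s)}
                for (k, v), s in zip(self.params.items(), self.se)
            },
            "f_tests": {k: v.to_dict() for k, v in self.f_tests.items()},
            "cell_means": self.cell_means.to_dict(orient="records"),
            "caveat": MULTIPLICITY_CAVEAT,
        }


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_group_time_model(
    data: pd.DataFrame,
    outcome_name: str,
    groups: list[str] | None = None,
    baseline_covariate: bool = False,
) -> MixedModelResult:
    """Fit the group x time linear mixed model for one outcome.

    ``data`` is long format with columns user_id, group, timepoint (0/6),
    outcome_name, value, sex, age, dup_days.  ``groups`` restricts the
    comparison (e.g. one profile vs TAU); default is every group present.
    ``baseline_covariate=True`` switches to the ANCOVA-style variant:
    6-month value regressed on group with the user's baseline value as a
    covariate (no random intercept needed: one row per user).
    """
    sub = data[data["outcome_name"] == outcome_name].copy()
    if sub.empty:
        raise ValueError(f"no rows for outcome {outcome_name!r}")
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    group_labels = sorted(sub["group"].unique())
    if len(group_labels) < 2:
        raise ValueError("need at least two groups")
    timepoints = sorted(sub["timepoint"].unique())
    if len(timepoints) != 2:
        raise ValueError(f"need exactly two timepoints, got {timepoints}")

    need = ["value", "sex", "age", "dup_days"]
    n_before = len(sub)
    sub = sub.dropna(subset=need)
    n_dropped = n_before - len(sub)

    if baseline_covariate:
        return _fit_ancova(sub, outcome_name, group_labels, timepoints, n_dropped)

    cov_means = {
        "sex": float(sub["sex"].mean()),
        "age": float(sub["age"].mean()),
        "dup_log": float(np.log(sub["dup_days"]).mean()),
    }
    design = _Design(
        groups=group_labels,
        timepoints=timepoints,
        colnames=_build_design(group_labels),
        cov_means=cov_means,
    )
    gcodes = sub["group"].map({g: i for i, g in enumerate(group_labels)}).to_numpy()
    tcodes = (sub["timepoint"] == timepoints[1]).astype(int).to_numpy()
    cov = np.column_stack(
        [
            sub["sex"].to_numpy(float) - cov_means["sex"],
            sub["age"].to_numpy(float) - cov_means["age"],
            np.log(sub["dup_days"].to_numpy(float)) - cov_means["dup_log"],
        ]
    )
    X = design.rows(gcodes, tcodes, cov)
    y = sub["value"].to_numpy(float)
    users, user_codes = np.unique(sub["user_id"], return_inverse=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=user_codes)
        fit = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:  # pragma: no cover - every optimizer failed
            raise RuntimeError(f"mixed-model fit failed for {outcome_name!r}")
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    singular = tau2 < 1e-8 * max(sigma2, 1e-12)
    beta = np.asarray(fit.fe_params)

    engine = _SatterthwaiteEngine(X, user_codes, sigma2, max(tau2, 0.0))
    se = np.sqrt(np.diag(engine.C))

    f_tests = {}
    for term in ("group", "time", "group:time"):
        L = design.term_selector(term)
        F, q, df2, p = engine.ftest(L, beta)
        f_tests[term] = ContrastResult(
            name=term, estimate=float("nan"), se=float("nan"),
            f_stat=F, df1=q, df2=df2, p_value=p,
        )

    cells = []
    for g in group_labels:
        for t in timepoints:
            x = design.cell_row(g, t)
            mean = float(x @ beta)
            var = float(x @ engine.C @ x)
            df = engine.df_1d(x)
            tcrit = stats.t.ppf(0.975, df)
            cells.append(
                {
                    "group": g,
                    "timepoint": t,
                    "mean": mean,
                    "se": np.sqrt(var),
                    "ci_low": mean - tcrit * np.sqrt(var),
                    "ci_high": mean + tcrit * np.sqrt(var),
                }
            )

    return MixedModelResult(
        outcome_name=outcome_name,
        groups=group_labels,
        params=pd.Series(beta, index=design.colnames),
        se=pd.Series(se, index=design.colnames),
        sigma2=sigma2,
        tau2=tau2,
        f_tests=f_tests,
        cell_means=pd.DataFrame(cells),
        n_obs=len(sub),
        n_users=len(users),
        n_dropped=n_dropped,
        converged=bool(getattr(fit, "converged", True)),
        singular=singular,
        design=design,
        engine=engine,
    )


def _fit_ancova(sub, outcome_name, group_labels, timepoints, n_dropped):
    """ANCOVA variant: follow-up value ~ group + baseline + covariates (OLS)."""
    wide = sub.pivot_table(
        index=["user_id", "group", "sex", "age", "dup_days"],
        columns="timepoint", values="value",
    ).reset_index()
    wide = wide.dropna(subset=timepoints)
    y = wide[timepoints[1]].to_numpy(float)
    gcodes = wide["group"].map({g: i for i, g in enumerate(group_labels)}).to_numpy()
    g = len(group_labels)
    cols = [np.ones(len(wide))]
    for j in range(g - 1):
        cols.append((gcodes == j).astype(float) - (gcodes == g - 1))
    cols.append(wide[timepoints[0]].to_numpy(float) - wide[timepoints[0]].mean())
    cols.append(wide["sex"].to_numpy(float) - wide["sex"].mean())
    cols.append(wide["age"].to_numpy(float) - wide["age"].mean())
    cols.append(np.log(wide["dup_days"].to_numpy(float))
                - np.log(wide["dup_days"]).mean())
    X = np.column_stack(cols)
    fit = sm.OLS(y, X).fit()
    L = np.zeros((g - 1, X.shape[1]))
    for r in range(g - 1):
        L[r, 1 + r] = 1.0
    ftest = fit.f_test(L)
    names = (["Intercept"] + [f"group[S.{lbl}]" for lbl in group_labels[:-1]]
             + ["baseline_c", "sex_c", "age_c", "dup_log_c"])
    group_test = ContrastResult(
        name="group|baseline", estimate=float("nan"), se=float("nan"),
        f_stat=float(ftest.fvalue), df1=int(ftest.df_num),
        df2=float(ftest.df_denom), p_value=float(ftest.pvalue),
    )
    cells = []
    for j, grp in enumerate(group_labels):
        x = np.zeros(X.shape[1])
        x[0] = 1.0
        if j < g - 1:
            x[1 + j] = 1.0
        else:
            x[1:g] = -1.0
        mean = float(x @ fit.params)
        se_ = float(np.sqrt(x @ fit.cov_params() @ x))
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        cells.append({"group": grp, "timepoint": timepoints[1], "mean": mean,
                      "se": se_, "ci_low": mean - tcrit * se_,
                      "ci_high": mean + tcrit * se_})
    return MixedModelResult(
        outcome_name=outcome_name, groups=group_labels,
        params=pd.Series(fit.params, index=names),
        se=pd.Series(fit.bse, index=names),
        sigma2=float(fit.scale), tau2=0.0,
        f_tests={"group|baseline": group_test},
        cell_means=pd.DataFrame(cells),
        n_obs=len(wide), n_users=len(wide), n_dropped=n_dropped,
        converged=True, singular=False,
    )


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

def _contrast(result: MixedModelResult, l: np.ndarray, name: str) -> ContrastResult:
    beta = result.params.to_numpy()
    est = float(l @ beta)
    var = float(l @ result.engine.C @ l)
    df2 = result.engine.df_1d(l)
    F = est * est / var if var > 0 else float("inf")
    return ContrastResult(
        name=name, estimate=est, se=float(np.sqrt(var)), f_stat=F,
        df1=1, df2=df2, p_value=float(stats.f.sf(F, 1, df2)),
    )


def posthoc_time_within_group(result: MixedModelResult, group: str) -> ContrastResult:
    """Single-df test of the baseline -> 6-month change within one group."""
    if result.design is None:
        raise ValueError("post-hoc contrasts need the mixed-model variant")
    if group not in result.groups:
        raise ValueError(f"unknown group {group!r}")
    t0, t1 = result.design.timepoints
    l = result.design.cell_row(group, t1) - result.design.cell_row(group, t0)
    return _contrast(result, l, f"time within {group}")


def posthoc_group_at_time(result: MixedModelResult, timepoint: int) -> list[ContrastResult]:
    """All pairwise group contrasts at one timepoint."""
    if result.design is None:
        raise ValueError("post-hoc contrasts need the mixed-model variant")
    if timepoint not in result.design.timepoints:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    out = []
    for i, g1 in enumerate(result.groups):
        for g2 in result.groups[i + 1:]:
            l = result.design.cell_row(g1, timepoint) - result.design.cell_row(
                g2, timepoint
            )
            out.append(_contrast(result, l, f"{g1} - {g2} at {timepoint}mo"))
    return out


# ---------------------------------------------------------------------------
# Baseline characterization
# ---------------------------------------------------------------------------

def anova_from_summary(ns, means, sds) -> tuple[float, int, int, float]:
    """One-way ANOVA F from per-group summary statistics.

    Closed form: F = [SSB/(k-1)] / [SSW/(N-k)] with
    SSB = sum n_i (m_i - grand)^2 and SSW = sum (n_i - 1) s_i^2.
    """
    ns = np.asarray(ns, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    k = len(ns)
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(N - k)
    F = (ssb / df1) / (ssw / df2)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


@dataclass
class CharacterizationResult:
    anova: dict[str, dict]
    chi_square: dict[str, dict]
    skipped: dict[str, str]

    def to_dict(self) -> dict:
        return {"anova": self.anova, "chi_square": self.chi_square,
                "skipped": self.skipped, "caveat": MULTIPLICITY_CAVEAT}


def characterize_profiles(
    baseline: pd.DataFrame,
    labels: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    alpha: float = 0.05,
) -> CharacterizationResult:
    """Compare profiles on baseline variables.

    ``baseline`` has one row per user (user_id + variables); ``labels`` maps
    user_id -> group.  Continuous variables get a one-way ANOVA with Tukey
    HSD pairwise contrasts when the omnibus test is significant at ``alpha``;
    categorical variables get a chi-square test of independence.  Variables
    where any group has fewer than 2 observations are skipped with a reason.
    """
    labels = labels.rename(columns={"archetype": "group"})
    merged = baseline.merge(labels[["user_id", "group"]], on="user_id")
    group_names = sorted(merged["group"].unique())
    if continuous is None:
        continuous = [
            c for c in baseline.columns
            if c != "user_id" and pd.api.types.is_numeric_dtype(baseline[c])
        ]
        categorical = categorical or [
            c for c in baseline.columns
            if c != "user_id" and not pd.api.types.is_numeric_dtype(baseline[c])
        ]
    categorical = categorical or []

    anova: dict[str, dict] = {}
    chi: dict[str, dict] = {}
    skipped: dict[str, str] = {}
    for var in continuous:
        samples = [
            merged.loc[merged["group"] == g, var].dropna().to_numpy()
            for g in group_names
        ]
        small = [g for g, s in zip(group_names, samples) if len(s) < 2]
        if small:
            skipped[var] = f"groups with n<2: {small}"
            continue
        F, p = stats.f_oneway(*samples)
        entry = {
            "F": float(F),
            "df": [len(samples) - 1, int(sum(map(len, samples)) - len(samples))],
            "p": float(p),
            "group_means": {g: float(s.mean()) for g, s in zip(group_names, samples)},
            "tukey": None,
        }
        if p < alpha:
            hsd = stats.tukey_hsd(*samples)
            pairs = []
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    pairs.append(
                        {
                            "pair": [group_names[i], group_names[j]],
                            "diff": float(samples[i].mean() - samples[j].mean()),
                            "p": float(hsd.pvalue[i, j]),
                        }
                    )
            entry["tukey"] = pairs
        anova[var] = entry
    for var in categorical:
        table = pd.crosstab(merged["group"], merged[var])
        if (table.sum(axis=1) < 2).any() or table.shape[1] < 2:
            skipped[var] = "insufficient category counts"
            continue
        chi2, p, df, _ = stats.chi2_contingency(table.to_numpy())
        chi[var] = {"chi2": float(chi2), "df": int(df), "p": float(p)}
    return CharacterizationResult(anova=anova, chi_square=chi, skipped=skipped)


# ---------------------------------------------------------------------------
# Table-style analysis across outcomes
# ---------------------------------------------------------------------------

def analyze_outcomes(
    outcomes: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    mode: str = "profiles",
    outcome_names: list[str] | None = None,
    fdr: bool = False,
    baseline_covariate: bool = False,
) -> dict:
    """Fit the group x time model for every outcome; mirror the trial tables.

    ``mode='profiles'`` compares the engagement profiles with each other;
    ``mode='each-vs-tau'`` fits one two-group model per profile against the
    TAU arm.  ``labels`` (user_id -> group) overrides any group column
    already present, so cluster assignments can be injected directly.
    ``fdr=True`` adds Benjamini-Hochberg-adjusted interaction p-values.
    """
    data = outcomes.copy()
    if labels is not None:
        lab = labels.rename(columns={"archetype": "group"})
        data = data.drop(columns=["group"], errors="ignore").merge(
            lab[["user_id", "group"]], on="user_id", how="left"
        )
        data["group"] = data["group"].fillna(
            data["arm"].map({"TAU": "TAU"}) if "arm" in data else np.nan
        )
    if "group" not in data.columns:
        raise ValueError("outcomes need a group column or labels mapping")
    data = data.dropna(subset=["group"])
    if outcome_names is None:
        outcome_names = sorted(data["outcome_name"].unique())

    profile_names = sorted(set(data["group"]) - {"TAU"})
    results: dict = {"mode": mode, "caveat": MULTIPLICITY_CAVEAT, "outcomes": {}}
    pvals: list[tuple[str, str, float]] = []
    for name in outcome_names:
        if mode == "profiles":
            res = fit_group_time_model(
                data, name, groups=profile_names,
                baseline_covariate=baseline_covariate,
            )
            entry = {"profiles": _summarize(res)}
            key = "group:time" if not baseline_covariate else "group|baseline"
            pvals.append((name, "profiles", entry["profiles"]["f_tests"][key]["p"]))
        elif mode == "each-vs-tau":
            entry = {}
            for prof in profile_names:
                res = fit_group_time_model(
                    data, name, groups=[prof, "TAU"],
                    baseline_covariate=baseline_covariate,
                )
                entry[prof] = _summarize(res)
                key = "group:time" if not baseline_covariate else "group|baseline"
                pvals.append((name, prof, entry[prof]["f_tests"][key]["p"]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        results["outcomes"][name] = entry
    if fdr and pvals:
        adj = multipletests([p for _, _, p in pvals], method="fdr_bh")[1]
        results["fdr_bh"] = {
            f"{name}/{which}": float(q) for (name, which, _), q in zip(pvals, adj)
        }
    return results


def _summarize(res: MixedModelResult) -> dict:
    out = res.to_dict()
    if res.design is not None:
        interaction = res.f_tests["group:time"]
        if interaction.p_value < 0.05:
            out["posthoc_time_within_group"] = {
                g: posthoc_time_within_group(res, g).to_dict() for g in res.groups
            }
            out["posthoc_group_at_time"] = {
                str(t): [c.to_dict() for c in posthoc_group_at_time(res, t)]
                for t in res.design.timepoints
            }
    return out
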
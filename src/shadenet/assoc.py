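"""Restricted two-stage multilocus association scan on gene–allele markers.

Stage 1 screens every marker with a single-locus fixed-effect regression
(environment as a blocking factor when multi-environment data are supplied)
and keeps markers with locus-term P <= alpha1.

Stage 2 runs deterministic forward/backward stepwise regression under a
multilocus model. Candidate terms are marker main effects and, optionally,
marker-by-environment interaction (GEI) terms; a GEI term is eligible only
while its main term is in the model, and a main term is shielded from
backward removal while its GEI term remains. Entry and stay use partial
F-tests against an experiment-wise threshold alpha2 / m (m = number of
markers scanned), which mirrors the Bonferroni-equivalent error control of
multilocus scans, and the summed marker contribution (R^2) is capped at the
trait's heritability. Allele effects are deviation coded (sum to zero within
a locus; for biparental markers the two alleles get +a and -a).

Per-marker contributions are sequential (entry-order) incremental sums of
squares over the total sum of squares; markers at or above 1.5% are classed
large-contribution (LC), the rest small-contribution (SC), and heritability
not covered by mapped markers is attributed to unmapped polygenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gasm import GASMSet

LC_THRESHOLD_PCT = 1.5


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def _align_y(y, line_ids: list[str]):
    """Normalize the phenotype input.

    Accepts a Series indexed by line (per-line means) or a DataFrame with
    columns line, value and optional env. Returns (y values, line index per
    observation, env codes per observation or None, env level labels).
    """
    pos = {l: i for i, l in enumerate(line_ids)}
    if isinstance(y, pd.Series):
        df = y.rename("value").rename_axis("line").reset_index()
    else:
        df = y.copy()
    if "line" not in df.columns or "value" not in df.columns:
        raise ValidationError("phenotype needs 'line' and 'value' columns")
    unknown = set(df["line"]) - set(pos)
    if unknown:
        raise ValidationError(f"phenotype lines not in genotypes: {sorted(unknown)[:3]}...")
    line_idx = df["line"].map(pos).to_numpy()
    yv = df["value"].to_numpy(float)
    if "env" in df.columns and df["env"].nunique() > 1:
        env_levels = sorted(df["env"].unique())
        env_codes = df["env"].map({e: i for i, e in enumerate(env_levels)}).to_numpy()
        return yv, line_idx, env_codes, env_levels
    return yv, line_idx, None, []


def _deviation_dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero coding: level j < k-1 -> e_j, last level -> -1 vector,
    negative codes (missing) -> all-zero row (population-mean imputation)."""
    n = codes.shape[0]
    out = np.zeros((n, max(n_levels - 1, 0)))
    for j in range(n_levels - 1):
        out[codes == j, j] = 1.0
    out[codes == n_levels - 1, :] = -1.0
    return out


def _base_design(n_obs: int, env_codes, n_env: int, covariates) -> np.ndarray:
    parts = [np.ones((n_obs, 1))]
    if env_codes is not None:
        parts.append(_deviation_dummies(env_codes, n_env))
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
    return np.concatenate(parts, axis=1)


def _fit_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _partial_f(rss_small: float, rank_small: int, rss_big: float, rank_big: int, n_obs: int):
    df_num = rank_big - rank_small
    df_den = n_obs - rank_big
    if df_num < 1 or df_den < 1:
        return None
    num = max(rss_small - rss_big, 0.0) / df_num
    if rss_big <= 0:
        return np.inf, 0.0, df_num, df_den
    f = num / (rss_big / df_den)
    return f, float(stats.f.sf(f, df_num, df_den)), df_num, df_den


# ---------------------------------------------------------------------------
# population-structure covariates
# ---------------------------------------------------------------------------


def eigen_covariates(gasmset: GASMSet, k: int = 10) -> np.ndarray:
    """Top-k eigenvectors of the line x line allele-sharing similarity matrix
    (fraction of markers with identical allele calls, pairwise-complete).

    k = 0 returns an empty covariate block — the sensible default for a
    biparental RIL panel, which has no population structure to correct.
    """
    n = len(gasmset.line_ids)
    if k >= n:
        raise ValidationError("k must be smaller than the number of lines")
    if k == 0:
        return np.zeros((n, 0))
    codes = gasmset.codes_matrix()  # (m, n)
    sim = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for row in codes:
        valid = row >= 0
        vv = np.outer(valid, valid)
        eq = np.equal.outer(row, row) & vv
        sim += eq
        cnt += vv
    with np.errstate(invalid="ignore"):
        S = np.where(cnt > 0, sim / np.maximum(cnt, 1), 0.0)
    w, v = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    return v[:, order[:k]]


# ---------------------------------------------------------------------------
# stage 1: single-locus screen
# ---------------------------------------------------------------------------


def stage1_preselect(
    gasmset: GASMSet,
    y,
    covariates: np.ndarray | None = None,
    alpha1: float = 0.05,
) -> pd.DataFrame:
    """Single-locus F-tests for every marker; keep P <= alpha1.

    ``y`` is a per-line Series or a long DataFrame (line, env, value); with
    multi-environment data the environment enters as a fixed blocking factor
    and only the marker main effect is screened. Markers with fewer than two
    observed alleles or fewer than three residual df are skipped.
    """
    yv, line_idx, env_codes, env_levels = _align_y(y, gasmset.line_ids)
    n_obs = yv.shape[0]
    cov_obs = covariates[line_idx] if covariates is not None and covariates.size else None
    X0 = _base_design(n_obs, env_codes, len(env_levels), cov_obs)
    rss0, rank0 = _fit_rss(X0, yv)

    rows = []
    for g in gasmset:
        codes_obs = g.codes[line_idx]
        observed = np.unique(codes_obs[codes_obs >= 0])
        if observed.size < 2:
            rows.append({"gene_id": g.gene_id, "F": np.nan, "P": np.nan, "kept": False, "reason": "monomorphic"})
            continue
        dummies = _deviation_dummies(codes_obs, g.n_alleles)
        X1 = np.concatenate([X0, dummies], axis=1)
        rss1, rank1 = _fit_rss(X1, yv)
        res = _partial_f(rss0, rank0, rss1, rank1, n_obs)
        if res is None or n_obs - rank1 < 3:
            rows.append({"gene_id": g.gene_id, "F": np.nan, "P": np.nan, "kept": False, "reason": "insufficient df"})
            continue
        f, p, *_ = res
        rows.append({"gene_id": g.gene_id, "F": f, "P": p, "kept": bool(p <= alpha1), "reason": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 2: stepwise multilocus fit
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    gene_id: str
    kind: str  # "main" | "gei"
    cols: np.ndarray


@dataclass
class MultilocusFit:
    """Final stepwise model: selected markers in entry order with deviation-
    coded allele (and allele x environment) effects."""

    gene_order: list[str]
    terms: list[tuple[str, str]]  # (gene_id, kind) in entry order
    mu: float
    env_levels: list[str]
    env_effects: np.ndarray  # per-env deviation effects (len n_env, sum 0)
    allele_effects: dict[str, np.ndarray]  # gene -> (n_alleles,), sum 0
    gei_effects: dict[str, np.ndarray]  # gene -> (n_alleles, n_env), sums 0
    covariate_coefs: np.ndarray
    sst: float
    rss: float
    n_obs: int
    rank: int
    locus_r2: float  # summed marker contribution as a fraction of SST
    r2_total: float
    residual_var: float
    # internals for sequential-R2 accounting
    _y: np.ndarray = field(repr=False, default=None)
    _X0: np.ndarray = field(repr=False, default=None)
    _term_objs: list = field(repr=False, default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.gene_order)


def _empty_fit(yv, X0, env_levels) -> MultilocusFit:
    rss0, rank0 = _fit_rss(X0, yv)
    sst = float(((yv - yv.mean()) ** 2).sum())
    n_env = len(env_levels)
    return MultilocusFit(
        gene_order=[],
        terms=[],
        mu=float(yv.mean()),
        env_levels=list(env_levels),
        env_effects=np.zeros(n_env),
        allele_effects={},
        gei_effects={},
        covariate_coefs=np.zeros(0),
        sst=sst,
        rss=rss0,
        n_obs=yv.shape[0],
        rank=rank0,
        locus_r2=0.0,
        r2_total=0.0 if sst == 0 else 1.0 - rss0 / sst,
        residual_var=rss0 / max(yv.shape[0] - rank0, 1),
        _y=yv,
        _X0=X0,
        _term_objs=[],
    )


def stage2_stepwise(
    y,
    gasmset: GASMSet,
    preselection: pd.DataFrame | list[str] | None = None,
    covariates: np.ndarray | None = None,
    alpha2: float = 0.05,
    h2_cap: float = 1.0,
    gei: bool = False,
    m_total: int | None = None,
) -> MultilocusFit:
    """Forward/backward stepwise multilocus regression with GEI hierarchy,
    experiment-wise error control and a heritability cap.

    ``preselection`` is the stage-1 table (kept rows used) or an explicit
    gene-id list; ``m_total`` is the number of markers the experiment scanned
    (defaults to the candidate count) and sets the entry/stay threshold
    alpha2 / m_total. A candidate enters only if its partial-F P passes the
    threshold *and* the updated summed marker R^2 stays within ``h2_cap``.
    Ties break on smallest P, then largest incremental SS, then genome order.
    """
    yv, line_idx, env_codes, env_levels = _align_y(y, gasmset.line_ids)
    n_obs = yv.shape[0]
    cov_obs = covariates[line_idx] if covariates is not None and covariates.size else None
    X0 = _base_design(n_obs, env_codes, len(env_levels), cov_obs)

    if preselection is None:
        candidate_genes = list(gasmset.gene_ids)
    elif isinstance(preselection, pd.DataFrame):
        candidate_genes = preselection.loc[preselection["kept"], "gene_id"].tolist()
    else:
        candidate_genes = list(preselection)
    index = {g.gene_id: i for i, g in enumerate(gasmset.gasms)}
    for g in candidate_genes:
        if g not in index:
            raise ValidationError(f"preselected gene {g!r} not in marker set")
    if gei and env_codes is None:
        gei = False  # no environments to interact with

    thr = alpha2 / max(m_total if m_total is not None else len(candidate_genes), 1)
    fit = _empty_fit(yv, X0, env_levels)
    if not candidate_genes or h2_cap <= 0 or fit.sst == 0:
        return fit

    n_env = len(env_levels)
    env_dev = _deviation_dummies(env_codes, n_env) if env_codes is not None else None

    def main_cols(gene):
        g = gasmset.gasms[index[gene]]
        return _deviation_dummies(g.codes[line_idx], g.n_alleles)

    def gei_cols(gene):
        a = main_cols(gene)
        # row-wise Kronecker of allele and environment deviation blocks
        return (a[:, :, None] * env_dev[:, None, :]).reshape(n_obs, -1)

    rss_base, rank_base = _fit_rss(X0, yv)
    sst = fit.sst
    model: list[_Term] = []

    def model_X(terms):
        if not terms:
            return X0
        return np.concatenate([X0] + [t.cols for t in terms], axis=1)

    rss_cur, rank_cur = rss_base, rank_base

    while True:
        # assemble candidate terms respecting the GEI hierarchy
        in_main = {t.gene_id for t in model if t.kind == "main"}
        in_gei = {t.gene_id for t in model if t.kind == "gei"}
        cands: list[_Term] = []
        for gene in candidate_genes:
            if gene not in in_main:
                cands.append(_Term(gene, "main", main_cols(gene)))
            elif gei and gene not in in_gei:
                cands.append(_Term(gene, "gei", gei_cols(gene)))
        if not cands:
            break

        best = None
        Xc = model_X(model)
        for order_idx, term in enumerate(cands):
            X_try = np.concatenate([Xc, term.cols], axis=1)
            rss_try, rank_try = _fit_rss(X_try, yv)
            res = _partial_f(rss_cur, rank_cur, rss_try, rank_try, n_obs)
            if res is None:
                continue  # aliased or out of df: skip
            f, p, *_ = res
            key = (p, -(rss_cur - rss_try), index[term.gene_id], 0 if term.kind == "main" else 1, order_idx)
            if best is None or key < best[0]:
                best = (key, term, rss_try, rank_try)
        if best is None:
            break
        key, term, rss_new, rank_new = best
        p_best = key[0]
        locus_r2_new = (rss_base - rss_new) / sst
        if p_best > thr or locus_r2_new > h2_cap + 1e-12:
            break
        model.append(term)
        rss_cur, rank_cur = rss_new, rank_new

        # backward scan: drop any removable term whose stay-P exceeds thr
        while True:
            gei_genes = {t.gene_id for t in model if t.kind == "gei"}
            worst = None
            for i, t in enumerate(model):
                if t.kind == "main" and t.gene_id in gei_genes:
                    continue  # shielded by its interaction term
                rest = model[:i] + model[i + 1:]
                rss_wo, rank_wo = _fit_rss(model_X(rest), yv)
                res = _partial_f(rss_wo, rank_wo, rss_cur, rank_cur, n_obs)
                if res is None:
                    continue
                _, p_stay, *_ = res
                if p_stay > thr and (worst is None or p_stay > worst[0]):
                    worst = (p_stay, i, rss_wo, rank_wo)
            if worst is None:
                break
            _, i, rss_wo, rank_wo = worst
            del model[i]
            rss_cur, rank_cur = rss_wo, rank_wo

    return _finalize(yv, X0, model, env_levels, env_codes, gasmset, index, line_idx,
                     cov_obs, rss_base, sst)


def _finalize(yv, X0, model, env_levels, env_codes, gasmset, index, line_idx, cov_obs,
              rss_base, sst) -> MultilocusFit:
    n_obs = yv.shape[0]
    n_env = len(env_levels)
    X = np.concatenate([X0] + [t.cols for t in model], axis=1) if model else X0
    beta = np.linalg.pinv(X) @ yv
    resid = yv - X @ beta
    rss = float(resid @ resid)
    rank = int(np.linalg.matrix_rank(X))

    ofs = 0
    mu = float(beta[ofs]); ofs += 1
    env_eff = np.zeros(n_env)
    if env_codes is not None and n_env > 1:
        coefs = beta[ofs: ofs + n_env - 1]; ofs += n_env - 1
        env_eff[: n_env - 1] = coefs
        env_eff[n_env - 1] = -coefs.sum()
    n_cov = 0 if cov_obs is None else cov_obs.shape[1]
    cov_coefs = np.array(beta[ofs: ofs + n_cov]); ofs += n_cov

    allele_effects: dict[str, np.ndarray] = {}
    gei_effects: dict[str, np.ndarray] = {}
    gene_order: list[str] = []
    for t in model:
        g = gasmset.gasms[index[t.gene_id]]
        k = g.n_alleles
        if t.kind == "main":
            coefs = beta[ofs: ofs + k - 1]; ofs += k - 1
            eff = np.empty(k)
            eff[: k - 1] = coefs
            eff[k - 1] = -coefs.sum()
            allele_effects[t.gene_id] = eff
            gene_order.append(t.gene_id)
        else:
            q = (k - 1) * (n_env - 1)
            gamma = np.asarray(beta[ofs: ofs + q]).reshape(k - 1, n_env - 1); ofs += q
            Ca = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
            Ce = np.vstack([np.eye(n_env - 1), -np.ones((1, n_env - 1))])
            gei_effects[t.gene_id] = Ca @ gamma @ Ce.T

    return MultilocusFit(
        gene_order=gene_order,
        terms=[(t.gene_id, t.kind) for t in model],
        mu=mu,
        env_levels=list(env_levels),
        env_effects=env_eff,
        allele_effects=allele_effects,
        gei_effects=gei_effects,
        covariate_coefs=cov_coefs,
        sst=sst,
        rss=rss,
        n_obs=n_obs,
        rank=rank,
        locus_r2=(rss_base - rss) / sst if sst > 0 else 0.0,
        r2_total=1.0 - rss / sst if sst > 0 else 0.0,
        residual_var=rss / max(n_obs - rank, 1),
        _y=yv,
        _X0=X0,
        _term_objs=list(model),
    )


# ---------------------------------------------------------------------------
# effect and contribution tables
# ---------------------------------------------------------------------------


def allele_effects(fit: MultilocusFit) -> pd.DataFrame:
    """Tidy per-allele effect table: main effects (term = 'main') and, when
    fitted, per-environment GEI effects (term = environment label)."""
    rows = []
    for gene, eff in fit.allele_effects.items():
        for a, e in enumerate(eff):
            rows.append({"gene_id": gene, "allele": a, "term": "main", "effect": float(e)})
        if gene in fit.gei_effects:
            mat = fit.gei_effects[gene]
            for a in range(mat.shape[0]):
                for e, env in enumerate(fit.env_levels):
                    rows.append({"gene_id": gene, "allele": a, "term": env, "effect": float(mat[a, e])})
    return pd.DataFrame(rows, columns=["gene_id", "allele", "term", "effect"])


def r2_table(fit: MultilocusFit, lc_threshold: float = LC_THRESHOLD_PCT) -> pd.DataFrame:
    """Per-marker contributions as sequential (entry-order) incremental sums
    of squares over the total SS, in percent, split into main and GEI parts,
    with the LC/SC class at ``lc_threshold`` (LC iff R2_main >= threshold)."""
    rows = {g: {"gene_id": g, "r2_main_pct": 0.0, "r2_gei_pct": 0.0} for g in fit.gene_order}
    X = fit._X0
    rss_prev, _ = _fit_rss(X, fit._y)
    for t in fit._term_objs:
        X = np.concatenate([X, t.cols], axis=1)
        rss_new, _ = _fit_rss(X, fit._y)
        inc = max(rss_prev - rss_new, 0.0) / fit.sst * 100.0 if fit.sst > 0 else 0.0
        key = "r2_main_pct" if t.kind == "main" else "r2_gei_pct"
        rows.setdefault(t.gene_id, {"gene_id": t.gene_id, "r2_main_pct": 0.0, "r2_gei_pct": 0.0})
        rows[t.gene_id][key] += inc
        rss_prev = rss_new
    out = pd.DataFrame(rows.values())
    if out.empty:
        return pd.DataFrame(columns=["gene_id", "r2_main_pct", "r2_gei_pct", "class"])
    out["class"] = [lc_class(v, lc_threshold) for v in out["r2_main_pct"]]
    return out


def lc_class(r2_main_pct: float, threshold: float = LC_THRESHOLD_PCT) -> str:
    """Large-contribution (LC) iff the main-effect contribution is at or
    above the threshold (default 1.5% of phenotypic variance), else SC."""
    return "LC" if r2_main_pct >= threshold else "SC"


def sequential_vs_partial_r2(fit: MultilocusFit) -> pd.DataFrame:
    """Diagnostic: entry-order sequential R2 next to last-entry partial R2
    per term. On near-orthogonal biparental designs the two agree closely."""
    seq = r2_table(fit)
    rows = []
    full_rss, full_rank = _fit_rss(
        np.concatenate([fit._X0] + [t.cols for t in fit._term_objs], axis=1) if fit._term_objs else fit._X0,
        fit._y,
    )
    for i, t in enumerate(fit._term_objs):
        rest = fit._term_objs[:i] + fit._term_objs[i + 1:]
        X_wo = np.concatenate([fit._X0] + [u.cols for u in rest], axis=1) if rest else fit._X0
        rss_wo, _ = _fit_rss(X_wo, fit._y)
        rows.append(
            {
                "gene_id": t.gene_id,
                "kind": t.kind,
                "partial_r2_pct": max(rss_wo - full_rss, 0.0) / fit.sst * 100.0,
            }
        )
    part = pd.DataFrame(rows)
    if part.empty:
        return pd.DataFrame(columns=["gene_id", "kind", "partial_r2_pct", "sequential_r2_pct"])
    seq_long = []
    for t in fit._term_objs:
        key = "r2_main_pct" if t.kind == "main" else "r2_gei_pct"
        seq_long.append(float(seq.loc[seq["gene_id"] == t.gene_id, key].iloc[0]))
    part["sequential_r2_pct"] = seq_long
    return part


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------


@dataclass
class PolygeneAccounting:
    """Heritability minus mapped-marker contributions, in percent."""

    h2_main_pct: float
    mapped_main_pct: float
    polygene_main_pct: float
    h2_gei_pct: float
    mapped_gei_pct: float
    polygene_gei_pct: float
    n_lc: int
    lc_total_pct: float
    n_sc: int
    sc_total_pct: float


def contribution_summary(
    table: pd.DataFrame,
    h2_main_pct: float,
    h2_gei_pct: float = 0.0,
    tol: float = 1e-6,
) -> PolygeneAccounting:
    """Polygene accounting: the part of heritability not covered by mapped
    markers. Raises if mapped contributions exceed the heritability beyond
    ``tol`` (the stepwise cap guarantees they cannot)."""
    mapped_main = float(table["r2_main_pct"].sum()) if len(table) else 0.0
    mapped_gei = float(table["r2_gei_pct"].sum()) if len(table) else 0.0
    rem_main = h2_main_pct - mapped_main
    rem_gei = h2_gei_pct - mapped_gei
    if rem_main < -tol:
        raise ValidationError(
            f"mapped main contributions ({mapped_main:.4f}%) exceed heritability ({h2_main_pct:.4f}%)"
        )
    lc = table[table["class"] == "LC"] if len(table) else table
    sc = table[table["class"] == "SC"] if len(table) else table
    return PolygeneAccounting(
        h2_main_pct=h2_main_pct,
        mapped_main_pct=mapped_main,
        polygene_main_pct=rem_main,
        h2_gei_pct=h2_gei_pct,
        mapped_gei_pct=mapped_gei,
        polygene_gei_pct=rem_gei,
        n_lc=int(len(lc)),
        lc_total_pct=float(lc["r2_main_pct"].sum()) if len(lc) else 0.0,
        n_sc=int(len(sc)),
        sc_total_pct=float(sc["r2_main_pct"].sum()) if len(sc) else 0.0,
    )


def union_count(n_a: int, n_b: int, n_shared: int) -> int:
    """Two-trait gene-union count n_a + n_b - shared."""
    if n_shared > min(n_a, n_b):
        raise ValidationError("shared count exceeds a trait's gene count")
    return n_a + n_b - n_shared
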
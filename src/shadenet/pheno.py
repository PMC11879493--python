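"""Shade-tolerance phenotype indicators, variance components, heritability.

Two indicators are supported, both dimensionless ratios where *smaller means
more shade tolerant*:

* STI (shade-tolerance index): the mean of the shade/control ratios of plant
  height (PH) and average internode length (AINL = PH / node number), taken
  per matched shade/control plot pair:

      STI = (PH_shade / PH_ck + AINL_shade / AINL_ck) / 2

* RCL (relative pith cell length): per shade micrograph, the mean pith-cell
  length divided by the pooled mean length over all control-micrograph cells
  of the same line.

Variance components come from the expected mean squares of the balanced
two-way random model (lines and environments random, plot-level error), and
broad-sense heritability on a line-mean basis uses

    h2 = sigma2_g / (sigma2_g + sigma2_ge / n + sigma2_eps / (n r))

with the single-environment reduction h2 = sigma2_g / (sigma2_g +
sigma2_eps / r) when only one environment is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError, PairingError, ValidationError


@dataclass(frozen=True)
class PlotRecord:
    line: str
    env: str
    rep: int
    condition: str  # "shade" or "control"
    PH: float  # plant height, cm
    NN: int  # main-stem node number

    def validate(self):
        if not (math.isfinite(self.PH) and self.PH > 0):
            raise ValidationError(f"PH must be finite and > 0, got {self.PH}")
        if self.NN < 1:
            raise ValidationError(f"NN must be >= 1, got {self.NN}")


def compute_sti(shade: PlotRecord, control: PlotRecord) -> float:
    """Shade-tolerance index for one matched shade/control plot pair."""
    shade.validate()
    control.validate()
    if shade.condition != "shade" or control.condition != "control":
        raise PairingError("records must be one shade and one control plot")
    if (shade.line, shade.env, shade.rep) != (control.line, control.env, control.rep):
        raise PairingError("shade and control plots must share (line, env, rep)")
    ainl_s = shade.PH / shade.NN
    ainl_c = control.PH / control.NN
    return (shade.PH / control.PH + ainl_s / ainl_c) / 2.0


def sti_table(plots: pd.DataFrame) -> pd.DataFrame:
    """Vectorized STI over a long-format plot table.

    ``plots`` needs columns line, env, rep, condition, PH, NN with exactly one
    shade and one control record per (line, env, rep). Returns a table with
    columns line, env, rep, value.
    """
    required = {"line", "env", "rep", "condition", "PH", "NN"}
    if not required.issubset(plots.columns):
        raise ValidationError(f"plot table needs columns {sorted(required)}")
    if (plots["PH"] <= 0).any() or (plots["NN"] < 1).any():
        raise ValidationError("PH must be > 0 and NN >= 1 for every plot")
    wide = plots.pivot_table(
        index=["line", "env", "rep"], columns="condition", values=["PH", "NN"], aggfunc="first"
    )
    for cond in ("shade", "control"):
        if ("PH", cond) not in wide.columns:
            raise PairingError(f"missing {cond} records")
    if wide.isna().any().any():
        raise PairingError("every (line, env, rep) needs both a shade and a control plot")
    ph_ratio = wide[("PH", "shade")] / wide[("PH", "control")]
    ainl_ratio = (wide[("PH", "shade")] / wide[("NN", "shade")]) / (
        wide[("PH", "control")] / wide[("NN", "control")]
    )
    out = ((ph_ratio + ainl_ratio) / 2.0).rename("value").reset_index()
    return out


def compute_rcl(
    shade_images: list[list[float]] | dict[str, list[float]],
    control_images: list[list[float]] | dict[str, list[float]],
) -> list[float]:
    """One relative cell length per shade micrograph.

    The denominator pools *all* control cells over all control micrographs
    (not a mean of image means, which differs when cell counts are unequal).
    """
    if isinstance(shade_images, dict):
        shade_images = [shade_images[k] for k in sorted(shade_images)]
    if isinstance(control_images, dict):
        control_images = [control_images[k] for k in sorted(control_images)]
    if not shade_images or not control_images:
        raise ValidationError("need at least one shade and one control micrograph")
    pooled = [length for img in control_images for length in img]
    if not pooled:
        raise ValidationError("control micrographs contain no cells")
    if any(l <= 0 for img in shade_images for l in img) or any(l <= 0 for l in pooled):
        raise ValidationError("cell lengths must be > 0")
    denom = float(np.mean(pooled))
    out = []
    for img in shade_images:
        if not img:
            raise ValidationError("empty shade micrograph")
        out.append(float(np.mean(img)) / denom)
    return out


def rcl_table(cells: pd.DataFrame, n_sample: int | None = 5, seed: int = 0) -> pd.DataFrame:
    """Per-line relative cell lengths from a long cell table.

    ``cells`` needs columns line, condition, image_id, length. One value per
    shade micrograph; when ``n_sample`` is given and a line has more shade
    micrographs than that, a seeded random subset of that size is kept
    (mirroring a workload-limited anatomical protocol). Returns columns line,
    rep, value.
    """
    required = {"line", "condition", "image_id", "length"}
    if not required.issubset(cells.columns):
        raise ValidationError(f"cell table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for line, grp in cells.groupby("line", sort=True):
        shade = grp[grp["condition"] == "shade"]
        ctrl = grp[grp["condition"] == "control"]
        shade_imgs = {im: sub["length"].tolist() for im, sub in shade.groupby("image_id")}
        ctrl_imgs = {im: sub["length"].tolist() for im, sub in ctrl.groupby("image_id")}
        values = compute_rcl(shade_imgs, ctrl_imgs)
        if n_sample is not None and len(values) > n_sample:
            keep = sorted(rng.choice(len(values), size=n_sample, replace=False))
            values = [values[i] for i in keep]
        for rep, v in enumerate(values, start=1):
            rows.append({"line": line, "rep": rep, "value": v})
    return pd.DataFrame(rows)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    n_env: int
    n_rep: int
    mu: float
    gei_estimable: bool = True
    truncated: bool = False  # any negative moment estimate clipped to 0


def anova_components(values: pd.DataFrame, design: dict | None = None) -> VarianceComponents:
    """Method-of-moments variance components for a balanced line x env x rep
    indicator table (columns line, env (optional), rep, value).

    Expected mean squares of the two-way random model give

        sigma2_g  = (MS_lines - MS_GE) / (n r)
        sigma2_ge = (MS_GE - MS_err) / r
        sigma2_eps = MS_err

    With a single environment the model reduces to one-way (sigma2_ge is not
    estimable and is reported as 0 with ``gei_estimable=False``). Negative
    moment estimates are truncated to 0 and flagged. Unbalanced layouts raise
    ``BalanceError``.
    """
    df = values.copy()
    if "env" not in df.columns:
        df["env"] = "E1"
    required = {"line", "env", "rep", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"indicator table needs columns {sorted(required)}")

    counts = df.groupby(["line", "env"], sort=False)["value"].size()
    if counts.nunique() != 1:
        raise BalanceError("unequal replication across (line, env) cells")
    r = int(counts.iloc[0])
    envs_per_line = df.groupby("line")["env"].nunique()
    if envs_per_line.nunique() != 1:
        raise BalanceError("unequal environment coverage across lines")
    n = int(envs_per_line.iloc[0])
    g = df["line"].nunique()
    if n * df["line"].nunique() != df.groupby(["line", "env"]).ngroups:
        raise BalanceError("incomplete line x env layout")
    if design is not None:
        if design.get("n_env", n) != n or design.get("n_rep", r) != r:
            raise BalanceError("stated design does not match the data layout")

    y = df["value"].to_numpy(float)
    grand = y.mean()
    line_means = df.groupby("line")["value"].mean()
    cell_means = df.groupby(["line", "env"])["value"].mean()

    truncated = False
    if n == 1:
        ss_g = r * ((line_means - grand) ** 2).sum()
        ms_g = ss_g / (g - 1)
        if r > 1:
            resid = y - df.groupby("line")["value"].transform("mean").to_numpy(float)
            ms_err = (resid**2).sum() / (g * (r - 1))
        else:
            raise BalanceError("single environment with a single replicate: error not estimable")
        s2_eps = ms_err
        s2_g = (ms_g - ms_err) / r
        if s2_g < 0:
            s2_g, truncated = 0.0, True
        return VarianceComponents(s2_g, 0.0, s2_eps, 1, r, float(grand), gei_estimable=False, truncated=truncated)

    if r < 2:
        raise BalanceError("plot-level error requires >= 2 replications")
    env_means = df.groupby("env")["value"].mean()
    ss_g = n * r * ((line_means - grand) ** 2).sum()
    ms_g = ss_g / (g - 1)
    interaction = (
        cell_means
        - line_means.reindex(cell_means.index.get_level_values("line")).to_numpy()
        - env_means.reindex(cell_means.index.get_level_values("env")).to_numpy()
        + grand
    )
    ms_ge = r * (interaction**2).sum() / ((g - 1) * (n - 1))
    resid = y - df.groupby(["line", "env"])["value"].transform("mean").to_numpy(float)
    ms_err = (resid**2).sum() / (g * n * (r - 1))

    s2_eps = ms_err
    s2_ge = (ms_ge - ms_err) / r
    s2_g = (ms_g - ms_ge) / (n * r)
    if s2_ge < 0:
        s2_ge, truncated = 0.0, True
    if s2_g < 0:
        s2_g, truncated = 0.0, True
    return VarianceComponents(s2_g, s2_ge, s2_eps, n, r, float(grand), gei_estimable=True, truncated=truncated)


def heritability(vc: VarianceComponents, with_gei: bool = True) -> dict:
    """Broad-sense heritability partition on a line-mean basis (fractions).

    Returns h2_main = sigma2_g / D, h2_gei = (sigma2_ge / n) / D and their
    sum h2_total, with D = sigma2_g + sigma2_ge/n + sigma2_eps/(n r). When
    GEI is not estimable (or ``with_gei=False``), the reduced single-
    environment denominator sigma2_g + sigma2_eps/r is used and h2_gei = 0.
    """
    if not vc.gei_estimable or not with_gei:
        D = vc.sigma2_g + vc.sigma2_eps / vc.n_rep
        if D == 0:
            raise ValidationError("zero phenotypic variance: heritability undefined")
        h2 = vc.sigma2_g / D
        return {"h2_total": h2, "h2_main": h2, "h2_gei": 0.0}
    D = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_eps / (vc.n_env * vc.n_rep)
    if D == 0:
        raise ValidationError("zero phenotypic variance: heritability undefined")
    h2_main = vc.sigma2_g / D
    h2_gei = (vc.sigma2_ge / vc.n_env) / D
    return {"h2_total": h2_main + h2_gei, "h2_main": h2_main, "h2_gei": h2_gei}


def gcv(sigma_g: float, mu: float) -> float:
    """Genotypic coefficient of variation sigma_g / mu."""
    if mu == 0:
        raise ValidationError("population mean is zero: GCV undefined")
    return sigma_g / mu
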
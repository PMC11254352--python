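"""Direct gene-environment interaction follow-up.

Once the scale tests have flagged trait-vQTL combinations, each is tested
directly against named environmental factors: an additive-genotype linear
model with a G x E product term, Wald test on the interaction coefficient.
The exposure under test is removed from the covariate set if present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DataError
from .data_io import SampleTable
from .scan import bonferroni_threshold

logger = logging.getLogger(__name__)


@dataclass
class GxEResult:
    trait: str
    snp_id: str
    env: str
    beta_int: float
    se: float
    p: float
    n_used: int


def direct_gxe_test(y: np.ndarray, g: np.ndarray, e: np.ndarray,
                    X: np.ndarray | None = None, *,
                    trait: str = "y", snp_id: str = "snp", env: str = "e",
                    robust: bool = False) -> GxEResult:
    """Wald test of the G x E term in  y ~ 1 + g + e + g*e + X.

    The genotype enters additively (0/1/2 allele count), not dummy-coded.
    ``robust=True`` switches to heteroskedasticity-consistent (HC3) standard
    errors — relevant here because variance effects are the signal under
    study.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    cols = [g, e, g * e]
    if X is not None and np.size(X):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        cols.extend(X.T)
    design = np.column_stack(cols)
    ok = ~(np.isnan(y) | np.isnan(design).any(axis=1))
    y, design = y[ok], design[ok]
    if np.nanstd(design[:, 1]) == 0:
        raise DataError(f"degenerate exposure {env!r}: constant over samples")
    design = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"{snp_id}x{env}")
    fit = sm.OLS(y, design).fit(cov_type="HC3" if robust else "nonrobust")
    idx = 3  # const, g, e, g*e
    return GxEResult(trait=trait, snp_id=snp_id, env=env,
                     beta_int=float(fit.params[idx]), se=float(fit.bse[idx]),
                     p=float(fit.pvalues[idx]), n_used=int(ok.sum()))


def gxe_grid(combinations: Sequence[tuple[str, str]], envs: Sequence[str],
             samples: SampleTable, genotypes: dict[str, np.ndarray],
             alpha: float = 0.05, robust: bool = False) -> pd.DataFrame:
    """Run the direct GxE test for every (trait, SNP) pair x environment.

    The significance threshold is alpha / (#pairs x #envs); the long-format
    output carries one row per cell with a ``significant`` mark, suitable
    for heatmap rendering.  Per-cell failures are logged and emitted with
    missing estimates.
    """
    if not combinations:
        raise DataError("gxe_grid requires at least one trait-SNP combination")
    threshold = bonferroni_threshold(alpha, len(combinations) * len(envs))
    rows = []
    for trait, snp_id in combinations:
        y = samples.Y[trait].to_numpy(dtype=float)
        g = genotypes[snp_id]
        for env in envs:
            e = samples.X[env].to_numpy(dtype=float)
            other = [c for c in samples.X.columns if c != env]
            X = samples.X[other].to_numpy(dtype=float) if other else None
            try:
                res = direct_gxe_test(y, g, e, X, trait=trait, snp_id=snp_id,
                                      env=env, robust=robust)
                rows.append({"trait": trait, "snp_id": snp_id, "env": env,
                             "beta_int": res.beta_int, "se": res.se,
                             "p": res.p, "n_used": res.n_used,
                             "significant": res.p < threshold})
            except (DataError, CollinearityError) as exc:
                logger.warning("gxe_grid cell (%s, %s, %s) failed: %s",
                               trait, snp_id, env, exc)
                rows.append({"trait": trait, "snp_id": snp_id, "env": env,
                             "beta_int": np.nan, "se": np.nan, "p": np.nan,
                             "n_used": 0, "significant": False})
    df = pd.DataFrame(rows)
    df.attrs["threshold"] = threshold
    return df


def effect_size_concordance(a: Sequence[GxEResult],
                            b: Sequence[GxEResult]) -> float:
    """Pearson correlation of interaction effect sizes across two cohorts,
    matched on (trait, snp, env) keys."""
    key = lambda r: (r.trait, r.snp_id, r.env)
    bmap = {key(r): r.beta_int for r in b}
    pairs = [(r.beta_int, bmap[key(r)]) for r in a if key(r) in bmap]
    if len(pairs) < 3:
        raise DataError(f"only {len(pairs)} matched (trait, snp, env) keys; "
                        "need >= 3 for a correlation")
    x, y = zip(*pairs)
    return float(stats.pearsonr(x, y).statistic)
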
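"""Weighted Z-score efficacy ranking of a compound x enzyme IC50 panel.

For each enzyme i, every successfully determined log10 IC50 is standardised
against the enzyme's own panel:

    z_i = (log10 IC50_i - Xbar_i) / s_i                               (1)

with Xbar_i the mean and s_i the standard deviation (sample, n-1 by
default) of the successful readouts for that enzyme.  A compound with no
readout for enzyme i is imputed z = 2 — a deliberately poor score that
still lets very weak inhibitors be ranked.  Per compound the scores are
combined as a weighted mean

    zbar = sum_i w_i z_i / panel_size                                 (2)
    w_i  = N_i / sum_i N_i                                            (3)

where N_i counts the successful readouts for enzyme i.  The division by
``panel_size`` (7 for the study's seven-enzyme panel) is implemented
literally even though the weights already sum to one; it is a constant
scale that preserves ranks and keeps zbar on the published scale.
Compounds screened multiple times get the average of their per-screen zbar
values.  Low zbar means high inhibition efficacy; ranking is ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import BASELINE
from .errors import DegenerateScaleError, InsufficientDataError

IMPUTED_Z = 2.0


@dataclass
class EnzymeZScoreSet:
    """Per-enzyme standardisation: panel statistics and per-compound z."""

    enzyme_id: str
    mean_log_ic50: float
    sd_log_ic50: float
    n_success: int
    z: pd.Series  # indexed by compound
    imputed: pd.Series  # boolean, aligned with z


def compute_enzyme_zscores(
    log_ic50: pd.Series, enzyme_id: str = "", ddof: int = 1
) -> EnzymeZScoreSet:
    """Standardise one enzyme's log10 IC50 column (NaN = no readout).

    Successful readouts get z = (x - Xbar)/s; missing ones are imputed
    z = 2.  Fewer than two successes leave s undefined and raise
    :class:`DegenerateScaleError`; the caller decides whether to drop the
    enzyme.
    """
    x = log_ic50.astype(float)
    ok = x.notna()
    n = int(ok.sum())
    if n < 2:
        raise DegenerateScaleError(
            f"enzyme {enzyme_id or '?'}: {n} successful readouts; scale undefined"
        )
    mean = float(x[ok].mean())
    sd = float(x[ok].std(ddof=ddof))
    if sd == 0.0:
        raise DegenerateScaleError(
            f"enzyme {enzyme_id or '?'}: zero spread among successful readouts"
        )
    z = (x - mean) / sd
    z[~ok] = IMPUTED_Z
    return EnzymeZScoreSet(
        enzyme_id=enzyme_id,
        mean_log_ic50=mean,
        sd_log_ic50=sd,
        n_success=n,
        z=z,
        imputed=~ok,
    )


def compute_weights(n_success: pd.Series) -> pd.Series:
    """Readout-count weights w_i = N_i / sum N_i over the enzyme panel."""
    n = n_success.astype(float)
    if (n < 0).any():
        raise ValueError("readout counts must be non-negative")
    total = n.sum()
    if total <= 0:
        raise InsufficientDataError("no successful readouts on any enzyme")
    return n / total


def compound_score(z: pd.Series, w: pd.Series, panel_size: int) -> float:
    """zbar = (sum_i w_i z_i) / panel_size, enzyme sets must match."""
    if set(z.index) != set(w.index):
        raise ValueError("z and w cover different enzyme sets")
    return float((w * z.reindex(w.index)).sum() / panel_size)


def score_panel(
    log_ic50_table: pd.DataFrame, panel_size: int | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Score every compound of a compounds x enzymes log10 IC50 table.

    NaN entries are failed readouts (imputed z = 2).  Enzymes with fewer
    than two successful readouts are dropped from both the z-scores and the
    weights.  ``panel_size`` defaults to the number of enzyme columns
    (before dropping), i.e. 7 for the study design.

    Returns a DataFrame indexed by compound with ``zbar`` plus per-enzyme
    ``z_<enzyme>``, ``imputed_<enzyme>`` and ``w_<enzyme>`` columns.
    """
    if log_ic50_table.shape[0] == 0 or log_ic50_table.shape[1] == 0:
        raise InsufficientDataError("empty panel")
    if panel_size is None:
        panel_size = log_ic50_table.shape[1]

    zsets = {}
    for enzyme in log_ic50_table.columns:
        try:
            zsets[enzyme] = compute_enzyme_zscores(
                log_ic50_table[enzyme], enzyme_id=str(enzyme), ddof=ddof
            )
        except DegenerateScaleError:
            continue
    if not zsets:
        raise InsufficientDataError("no enzyme has >= 2 successful readouts")

    n_success = pd.Series({e: zs.n_success for e, zs in zsets.items()})
    w = compute_weights(n_success)
    zmat = pd.DataFrame({e: zs.z for e, zs in zsets.items()})
    imput = pd.DataFrame({e: zs.imputed for e, zs in zsets.items()})
    zbar = zmat.mul(w, axis=1).sum(axis=1) / panel_size

    out = pd.DataFrame({"zbar": zbar})
    for e in zsets:
        out[f"z_{e}"] = zmat[e]
        out[f"imputed_{e}"] = imput[e]
        out[f"w_{e}"] = w[e]
    return out


def rank_compounds(
    fits: pd.DataFrame,
    panel_size: int | None = None,
    ddof: int = 1,
    include_extrapolated: bool = True,
) -> pd.DataFrame:
    """Full ranking from a fits table (output of ``dose_response.fit_panel``).

    Successful readouts are IN_RANGE fits plus, by default, EXTRAPOLATED
    ones (their extrapolated IC50 is used); BASELINE fits count as "no
    readout" and are imputed z = 2.  If a ``repeat`` column is present,
    each repeat screen is scored separately and a compound's zbar values
    are averaged across repeats.  Compounds are sorted ascending by zbar
    (low zbar = high efficacy); ties are broken lexicographically by
    compound id and flagged.
    """
    if len(fits) == 0:
        raise InsufficientDataError("empty fits table")
    fits = fits.copy()
    success = fits["category"] != BASELINE
    if not include_extrapolated:
        success &= fits["category"] == "IN_RANGE"
    fits["log10_ic50_success"] = np.where(success, fits["log10_ic50"], np.nan)

    repeat_col = "repeat" if "repeat" in fits.columns else None
    scored_parts = []
    groups = fits.groupby(repeat_col) if repeat_col else [(0, fits)]
    for rep, part in groups:
        table = part.pivot_table(
            index="compound_id",
            columns="enzyme_id",
            values="log10_ic50_success",
            aggfunc="mean",
            dropna=False,
        )
        scores = score_panel(table, panel_size=panel_size, ddof=ddof)
        scores["repeat"] = rep
        scored_parts.append(scores)
    scored = pd.concat(scored_parts)

    agg = scored.groupby(level=0).agg(
        zbar=("zbar", "mean"), n_repeats_averaged=("zbar", "size")
    )
    # stable sort: lexicographic compound id breaks zbar ties
    agg = agg.sort_index(kind="mergesort").sort_values("zbar", kind="mergesort")
    agg["rank"] = np.arange(1, len(agg) + 1)
    agg["tied"] = agg["zbar"].duplicated(keep=False)
    # attach per-enzyme detail from the first repeat for reporting
    detail = scored_parts[0].drop(columns=["repeat"])
    out = agg.join(detail.drop(columns=["zbar"]), how="left")
    out.index.name = "compound_id"
    return out
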
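"""Splicing yield: the fraction of precursor RNA converted to spliced
product.

For a splice site the yield eta is the summed synthesis rate of all
junction bonds using that site divided by the synthesis rate of the site
bond itself.  A yield of 1 means every synthesized precursor is spliced;
below 1, part of the precursor pool is degraded without productive exon
ligation.  Estimation noise can push eta above 1 and the estimate is
deliberately not clipped.  The acceptor-side yield is the default report
because acceptor kinetics carry no transcription delay, making its
synthesis rate the more robust denominator; the junction synthesis rates
are taken from the coupled model and the site rate from the first-order
model for the same reason.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def splicing_yield(junction_alphas, site_alpha: float) -> float:
    """eta = sum of junction synthesis rates / site synthesis rate.

    An empty junction set yields 0.  Values above 1 are reported as-is.
    """
    if site_alpha is None or not np.isfinite(site_alpha) or site_alpha <= 0:
        raise ValueError("site synthesis rate must be positive and finite")
    junction_alphas = np.asarray(list(junction_alphas), dtype=float)
    if junction_alphas.size == 0:
        return 0.0
    return float(junction_alphas.sum() / site_alpha)


def yield_table(
    junction_rates: pd.DataFrame,
    site_rates: pd.DataFrame,
    junction_to_site: pd.DataFrame,
    site_type: str = "acceptor",
) -> pd.DataFrame:
    """Aggregate junction synthesis rates per site and form yields.

    Parameters
    ----------
    junction_rates
        Per-junction fits with columns ``bond_id`` and ``alpha`` (coupled
        model feed rate), plus optionally ``status``.
    site_rates
        Per-site first-order fits with ``bond_id`` and ``alpha``.
    junction_to_site
        Mapping with columns ``junction_id`` and ``site_id``; several
        junctions may share one site (alternative partners).
    site_type
        Reported in the output; "acceptor" (default) or "donor".

    Junctions with failed fits (or missing from ``junction_rates``) are
    excluded from the sum and counted in ``n_junctions_missing`` so partial
    sums are visible.  Sites without a rate estimate are omitted.
    """
    jr = junction_rates.set_index("bond_id")
    if "status" in jr.columns:
        ok = jr["status"] == "ok"
    else:
        ok = pd.Series(True, index=jr.index)
    sr = site_rates.set_index("bond_id")["alpha"]
    rows = []
    for site_id, grp in junction_to_site.groupby("site_id"):
        if site_id not in sr.index or not np.isfinite(sr[site_id]) or sr[site_id] <= 0:
            continue
        jids = grp["junction_id"].tolist()
        present = [j for j in jids if j in jr.index and ok.get(j, False) and np.isfinite(jr.loc[j, "alpha"])]
        alphas = jr.loc[present, "alpha"].to_numpy() if present else np.empty(0)
        rows.append(
            {
                "site_id": site_id,
                "site_type": site_type,
                "eta": splicing_yield(alphas, float(sr[site_id])),
                "n_junctions": len(present),
                "n_junctions_missing": len(jids) - len(present),
                "junction_ids": ",".join(present),
            }
        )
    return pd.DataFrame(rows)
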
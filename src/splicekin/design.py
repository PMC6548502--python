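"""Labeling design: which samples exist, their protocol and 4sU duration.

The study design is TT-seq and total RNA-seq performed after 2, 5, 10, 15,
20, 30 and 60 min of 4sU labeling, two biological replicates each -- 28
samples in total.  RNA-seq samples measure the steady state; their nominal
labeling duration is carried along for bookkeeping but plays no role in the
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_DURATIONS = (2, 5, 10, 15, 20, 30, 60)
PROTOCOLS = ("ttseq", "rnaseq")


def default_design(durations=DEFAULT_DURATIONS, n_replicates: int = 2) -> pd.DataFrame:
    """The study's sample layout: both protocols x durations x replicates."""
    rows = []
    for protocol in PROTOCOLS:
        for t in durations:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{protocol}_{t}min_rep{rep}",
                        "protocol": protocol,
                        "labeling_minutes": t,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignArrays:
    """Per-sample vectors consumed by the kinetic likelihoods.

    Attributes
    ----------
    sample_id : array of str
    t : labeling duration in minutes (meaningful for TT-seq only)
    is_ttseq : boolean mask
    F : depth / labeled-fraction normalization factor, > 0
    chi : cross-contamination fraction; exactly 1 for RNA-seq samples
    """

    sample_id: np.ndarray
    t: np.ndarray
    is_ttseq: np.ndarray
    F: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        if np.any(self.F <= 0):
            raise ValueError("normalization factors F must be positive")
        if np.any((self.chi <= 0) | (self.chi > 1)):
            raise ValueError("cross-contamination chi must lie in (0, 1]")
        if not np.allclose(self.chi[~self.is_ttseq], 1.0):
            raise ValueError("chi must be exactly 1 for RNA-seq samples")
        if np.any(self.t[self.is_ttseq] <= 0):
            raise ValueError("TT-seq labeling durations must be positive")

    @property
    def n_samples(self) -> int:
        return self.sample_id.size


def design_arrays(design: pd.DataFrame, factors: pd.DataFrame) -> DesignArrays:
    """Join a design table with fitted factors into aligned vectors.

    ``design`` needs columns sample_id, protocol, labeling_minutes;
    ``factors`` needs sample_id, F, chi.  Samples present in the design but
    missing from the factors raise.
    """
    merged = design.merge(factors[["sample_id", "F", "chi"]], on="sample_id", how="left")
    if merged["F"].isna().any():
        missing = merged.loc[merged["F"].isna(), "sample_id"].tolist()
        raise ValueError(f"no normalization factors for samples: {missing}")
    is_tt = merged["protocol"].to_numpy() == "ttseq"
    chi = merged["chi"].to_numpy(dtype=float).copy()
    chi[~is_tt] = 1.0
    return DesignArrays(
        sample_id=merged["sample_id"].to_numpy(),
        t=merged["labeling_minutes"].to_numpy(dtype=float),
        is_ttseq=is_tt,
        F=merged["F"].to_numpy(dtype=float),
        chi=chi,
    )
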
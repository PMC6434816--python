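"""Contamination rates and contamination-corrected expression.

Host contamination of a pearl-sac sample is the complement of its
normalized donor-specific SNV read rate:

    contamination (%) = 100 − normalized donor-specific SNV rate (%)

and expression measured in the mixed tissue is rescaled to the pure
donor (pearl-sac) scale by

    adjusted TPM = TPM × 100 / (100 − contamination (%))

which is exact for transcripts expressed only in donor tissue, as the
biomineralization panel genes are. A contamination of 100% would make the
divisor zero, so estimates reaching 100 are capped (default 99.9%) with a
warning. Adjusted columns are not re-closed to sum to 10⁶: adjusted values
are comparable abundances, not a renormalized composition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MetadataError

logger = logging.getLogger(__name__)

#: Columns of the per-sample contamination table.
CONTAMINATION_COLUMNS = (
    "sample_id", "normalized_rate_percent", "contamination_percent",
    "donor_fraction", "capped",
)

DEFAULT_CAP = 99.9


def contamination_from_rates(
    rates: pd.DataFrame, cap: float = DEFAULT_CAP
) -> pd.DataFrame:
    """Per-sample contamination estimates from normalized SNV rates.

    contamination_percent = 100 − normalized_rate_percent, capped at
    ``cap`` (so the adjustment divisor is never zero); donor_fraction =
    (100 − contamination) / 100. Missing rates propagate as missing.
    """
    if not 0 < cap < 100:
        raise ValueError(f"cap must be in (0, 100), got {cap}")
    norm = rates["normalized_rate_percent"].astype(float)
    contamination = 100.0 - norm
    capped = contamination > cap
    n_capped = int(capped.fillna(False).sum())
    if n_capped:
        logger.warning(
            "capped %d contamination estimate(s) at %.1f%% (normalized rate "
            "at or near 0)", n_capped, cap,
        )
    contamination = contamination.where(~capped.fillna(False), cap)
    out = pd.DataFrame(
        dict(
            sample_id=rates["sample_id"],
            normalized_rate_percent=norm,
            contamination_percent=contamination,
            donor_fraction=(100.0 - contamination) / 100.0,
            capped=capped.fillna(False),
        )
    )
    return out


def adjust_expression(tpm: float, contamination_percent: float) -> float:
    """Rescale one TPM value to the pure-donor scale."""
    if contamination_percent >= 100:
        raise ValueError(
            f"contamination must be < 100%, got {contamination_percent}"
        )
    # factor first: contamination 0 must give exactly tpm
    return tpm * (100.0 / (100.0 - contamination_percent))


def adjust_matrix(
    matrix: pd.DataFrame,
    estimates: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Contamination-correct a gene × sample TPM matrix.

    Each sample column is multiplied by its scalar factor
    ``100 / (100 − contamination)``. Columns whose sample has a missing
    estimate are left unadjusted and recorded in
    ``result.attrs["unadjusted_samples"]``; a column absent from both the
    estimates and the metadata raises. Gene order is preserved.
    """
    est = estimates.set_index("sample_id")["contamination_percent"]
    known = set(est.index)
    if metadata is not None:
        known |= set(metadata["sample_id"])
    unknown = [s for s in matrix.columns if s not in known]
    if unknown:
        raise MetadataError(
            f"samples in expression matrix with no contamination estimate "
            f"or metadata entry: {unknown}"
        )

    out = matrix.copy()
    unadjusted = []
    for sample in matrix.columns:
        c = est.get(sample, np.nan)
        if pd.isna(c):
            unadjusted.append(sample)
            continue
        out[sample] = matrix[sample] * (100.0 / (100.0 - float(c)))
    if unadjusted:
        logger.warning(
            "left %d sample column(s) unadjusted (missing estimate): %s",
            len(unadjusted), unadjusted,
        )
    out.attrs["adjusted"] = True
    out.attrs["unadjusted_samples"] = unadjusted
    return out
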
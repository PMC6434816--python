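"""Grafting time-course design shared across the pipeline.

The experiment follows mantle allografting in the pearl oyster *Pinctada
fucata*: mantle tissue from a donor oyster is implanted into host oysters,
and the implanted tissue (eventually a pearl sac) is sampled over three
months. Nine sampling points span the course: three donor-pure tissues taken
before or at grafting (``cell`` = donor mantle epithelial cells, ``before`` =
donor mantle pallium, ``0h`` = graft tissue at transplantation) and six
post-graft pearl-sac samples (``24h`` … ``3m``) that are increasingly
contaminated with host gonad tissue.
"""

from __future__ import annotations

import pandas as pd

from .errors import MetadataError

#: Canonical time-point order of the grafting course.
TIME_POINTS: tuple[str, ...] = (
    "cell", "before", "0h", "24h", "48h", "1w", "2w", "1m", "3m",
)

#: Time points whose samples are donor tissue only (host fraction is zero by design).
PURE_DONOR_TIME_POINTS: tuple[str, ...] = ("cell", "before", "0h")

#: Time points sampled from pearl sacs grown inside host oysters.
GRAFTED_TIME_POINTS: tuple[str, ...] = ("24h", "48h", "1w", "2w", "1m", "3m")

#: The reference time point: donor-specific SNVs are defined against it and
#: its donor-specific SNV read rate anchors the 100% normalization.
REFERENCE_TIME_POINT = "0h"

METADATA_COLUMNS = ("sample_id", "donor_id", "time_point", "replicate", "is_reference")


def load_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV and validate its structure."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata is missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids in metadata: {dupes}")
    unknown = set(meta["time_point"]) - set(TIME_POINTS)
    if unknown:
        raise MetadataError(f"unknown time point labels: {sorted(unknown)}")
    meta = meta.copy()
    meta["is_reference"] = meta["is_reference"].astype(bool)
    return meta


def reference_sample(meta: pd.DataFrame, donor_id: str) -> str:
    """Return the sample id of the donor's single 0 h reference sample."""
    refs = meta[(meta["donor_id"] == donor_id) & meta["is_reference"]]
    if len(refs) != 1:
        raise MetadataError(
            f"donor {donor_id!r} must have exactly one reference sample, "
            f"found {len(refs)}"
        )
    row = refs.iloc[0]
    if row["time_point"] != REFERENCE_TIME_POINT:
        raise MetadataError(
            f"reference sample {row['sample_id']!r} of donor {donor_id!r} is at "
            f"time point {row['time_point']!r}, expected {REFERENCE_TIME_POINT!r}"
        )
    return str(row["sample_id"])


def time_point_sort_key(tp: str) -> int:
    return TIME_POINTS.index(tp)
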
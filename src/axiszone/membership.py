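"""Composite zone-membership codes and category summaries.

A transcript is specific to a zone when its one-vs-rest test is
significant (q <= alpha) with positive logFC.  The zones it is specific to
are joined into a dotted code ordered by normalized expression, highest
first: "2.1" means specific to zones 1 and 2 with higher expression in
zone 2, "1.2" the same zones with higher expression in zone 1.  A
transcript restricted to no zone gets the code "none".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "MembershipCode",
    "CategorySummary",
    "assign_membership",
    "assign_membership_all",
    "summarize_categories",
    "order_for_heatmap",
    "NONE_CODE",
]

NONE_CODE = "none"


@dataclasses.dataclass(frozen=True)
class MembershipCode:
    """Ordered composite code naming the zones a transcript is specific to."""

    zones: tuple[str, ...]

    @property
    def code(self) -> str:
        return ".".join(self.zones) if self.zones else NONE_CODE

    @classmethod
    def from_code(cls, code: str) -> "MembershipCode":
        if code == NONE_CODE or code == "":
            return cls(())
        return cls(tuple(code.split(".")))

    def __post_init__(self) -> None:
        if len(set(self.zones)) != len(self.zones):
            raise ValueError("membership code repeats a zone")

    def __str__(self) -> str:
        return self.code


@dataclasses.dataclass
class CategorySummary:
    """Counts of transcripts per membership code.

    ``counts`` includes the "none" bin, so its values sum to the number of
    transcripts analyzed.  ``n_categories`` counts distinct non-"none"
    codes and ``n_multi`` those naming more than one zone.
    """

    counts: dict[str, int]
    n_restricted: int
    n_categories: int
    n_multi: int

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["code", "n_transcripts"])


def assign_membership(
    records: pd.DataFrame,
    cpm_row: np.ndarray | pd.Series,
    alpha: float,
    zone_labels: list[str] | None = None,
) -> MembershipCode:
    """Membership code for one transcript from its per-zone test records.

    ``records`` holds one row per zone with columns ``zone``, ``logFC``,
    ``p_value``, ``q_value``; ``cpm_row`` the transcript's normalized CPM
    per zone in axial order.  Zones with q <= alpha and logFC > 0 are
    selected and ordered by CPM descending; ties broken by smaller
    p-value, then anterior first.
    """
    if zone_labels is None:
        zone_labels = list(records["zone"])
    by_zone = records.set_index("zone")
    missing = [z for z in zone_labels if z not in by_zone.index]
    if missing or len(records) != len(zone_labels):
        raise ValueError(f"need exactly one record per zone; missing {missing}")
    cpm_row = np.asarray(cpm_row, dtype=float)
    if cpm_row.shape != (len(zone_labels),):
        raise ValueError("cpm_row length must match the zone set")
    selected = []
    for i, z in enumerate(zone_labels):
        rec = by_zone.loc[z]
        if rec["q_value"] <= alpha and rec["logFC"] > 0:
            selected.append((-cpm_row[i], rec["p_value"], i, z))
    selected.sort()
    return MembershipCode(tuple(z for *_, z in selected))


def assign_membership_all(
    records: pd.DataFrame,
    cpm: np.ndarray,
    transcript_ids: list[str],
    zone_labels: list[str],
    alpha: float,
) -> pd.Series:
    """Vectorised membership codes for a full one-vs-rest record table."""
    n_g, n_z = len(transcript_ids), len(zone_labels)
    wide = records.pivot(index="transcript_id", columns="zone")
    q = wide["q_value"].reindex(index=transcript_ids, columns=zone_labels).to_numpy()
    lfc = wide["logFC"].reindex(index=transcript_ids, columns=zone_labels).to_numpy()
    p = wide["p_value"].reindex(index=transcript_ids, columns=zone_labels).to_numpy()
    if np.isnan(q).any():
        raise ValueError("missing (transcript, zone) records")
    hit = (q <= alpha) & (lfc > 0)
    codes = []
    for g in range(n_g):
        idx = np.flatnonzero(hit[g])
        order = sorted(idx, key=lambda i: (-cpm[g, i], p[g, i], i))
        codes.append(MembershipCode(tuple(zone_labels[i] for i in order)).code)
    return pd.Series(codes, index=transcript_ids, name="code")


def summarize_categories(codes: pd.Series | list[str]) -> CategorySummary:
    """Exact per-code transcript counts and restriction totals."""
    codes = pd.Series(list(codes), dtype=str)
    counts = codes.value_counts().to_dict()
    non_none = {c: n for c, n in counts.items() if c != NONE_CODE}
    return CategorySummary(
        counts={str(c): int(n) for c, n in counts.items()},
        n_restricted=int(sum(non_none.values())),
        n_categories=len(non_none),
        n_multi=sum(1 for c in non_none if "." in c),
    )


def order_for_heatmap(
    codes: pd.Series,
    cpm: np.ndarray,
    zone_labels: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Row ordering and row-scaled CPM for a membership heatmap.

    Transcripts are grouped by primary (first-listed) zone in axial order
    with "none" last; within a group, sorted by primary-zone CPM
    descending.  Each returned row is divided by its own maximum, so kept
    rows lie in [0, 1] with max exactly 1 (all-zero rows stay zero).
    """
    cpm = np.asarray(cpm, dtype=float)
    zone_rank = {z: i for i, z in enumerate(zone_labels)}
    keys = []
    for g, code in enumerate(codes):
        if code == NONE_CODE:
            keys.append((len(zone_labels), 0.0, g))
        else:
            primary = code.split(".")[0]
            keys.append((zone_rank[primary], -cpm[g, zone_rank[primary]], g))
    order = np.array([g for *_, g in sorted(keys)], dtype=int)
    scaled = cpm[order].copy()
    row_max = scaled.max(axis=1)
    positive = row_max > 0
    scaled[positive] /= row_max[positive, np.newaxis]
    return order, scaled
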
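"""Node (region) table handling: load, validate, filter, merge.

The network's nodes come from an anatomical parcellation described by a
tabular file with one row per region.  Regions can be excluded by
anatomical class (e.g. cerebellar regions outside the field of view) or by
size (small regions are noisy), and small-but-important subregions can be
retained by collapsing them into a single composite node via a shared
``merge_group`` key (e.g. all thalamic subnuclei become one thalamus node).
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

HEMISPHERES = {"left", "right", "bilateral"}
LOBES = {
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "cingulate",
    "subcortical",
    "insula",
    "other",
}
REGION_CLASSES = {"cortical", "subcortical", "cerebellar"}

REQUIRED_COLUMNS = [
    "region_id",
    "name",
    "hemisphere",
    "lobe",
    "size_voxels",
    "region_class",
    "merge_group",
]


class NodeTableError(ValueError):
    """Raised when a node table violates its schema or invariants."""


def validate_node_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a node table against the schema; returns a normalized copy.

    Checks required columns, closed vocabularies for ``hemisphere``,
    ``lobe`` and ``region_class``, uniqueness of ``region_id`` and
    non-negative integer sizes.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise NodeTableError(f"node table missing required column(s): {missing}")
    t = table.loc[:, REQUIRED_COLUMNS].copy()
    t["region_id"] = t["region_id"].astype(str)
    t["name"] = t["name"].astype(str)
    t["merge_group"] = t["merge_group"].fillna("").astype(str)

    dup = t["region_id"][t["region_id"].duplicated()].unique().tolist()
    if dup:
        raise NodeTableError(f"duplicate region_id values: {dup}")

    for col, vocab in (
        ("hemisphere", HEMISPHERES),
        ("lobe", LOBES),
        ("region_class", REGION_CLASSES),
    ):
        bad = sorted(set(t[col].astype(str)) - vocab)
        if bad:
            raise NodeTableError(f"unknown {col} value(s): {bad}; allowed: {sorted(vocab)}")

    sizes = pd.to_numeric(t["size_voxels"], errors="raise")
    if (sizes < 0).any() or (sizes != sizes.astype(int)).any():
        raise NodeTableError("size_voxels must be non-negative integers")
    t["size_voxels"] = sizes.astype(int)
    return t.reset_index(drop=True)


def load_node_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a node table from a TSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"node table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table["merge_group"] = table.get("merge_group", "")
    return validate_node_table(table)


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def apply_exclusions(
    table: pd.DataFrame,
    min_size_voxels: int = 57,
    excluded_classes: set[str] | frozenset[str] = frozenset({"cerebellar"}),
) -> pd.DataFrame:
    """Drop regions by anatomical class and by voxel size.

    Regions strictly smaller than ``min_size_voxels`` are dropped unless
    they carry a ``merge_group`` key: small subregions slated for merging
    are retained so the composite node can be formed.  Row order is
    preserved.
    """
    if min_size_voxels < 0:
        raise ValueError("min_size_voxels must be >= 0")
    t = validate_node_table(table)
    keep_class = ~t["region_class"].isin(set(excluded_classes))
    big_enough = t["size_voxels"] >= min_size_voxels
    mergeable = t["merge_group"] != ""
    out = t[keep_class & (big_enough | mergeable)].reset_index(drop=True)
    if len(out) < 2:
        raise NodeTableError(
            f"exclusions left {len(out)} region(s); a network needs at least 2 nodes"
        )
    return out


def apply_merges(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Collapse rows sharing a ``merge_group`` key into composite nodes.

    The composite node takes the merge-group key as its ``region_id`` and
    ``name``, sums member sizes, and requires homogeneous ``lobe`` and
    ``region_class`` within the group.  Hemisphere may differ, in which
    case the composite is ``bilateral``.  Returns the merged table and a
    map from original region ids to final node ids (identity for unmerged
    rows), used to aggregate time-series columns.
    """
    t = validate_node_table(table)
    merge_map: dict[str, str] = {}
    rows = []
    seen_groups: set[str] = set()
    for _, row in t.iterrows():
        g = row["merge_group"]
        if g == "":
            merge_map[row["region_id"]] = row["region_id"]
            rows.append(row)
            continue
        merge_map[row["region_id"]] = g
        if g in seen_groups:
            continue
        seen_groups.add(g)
        members = t[t["merge_group"] == g]
        for col in ("lobe", "region_class"):
            vals = members[col].unique()
            if len(vals) > 1:
                raise NodeTableError(
                    f"merge group {g!r} mixes {col} values {sorted(vals)}"
                )
        hemis = set(members["hemisphere"])
        hemi = hemis.pop() if len(hemis) == 1 else "bilateral"
        rows.append(
            pd.Series(
                {
                    "region_id": g,
                    "name": g,
                    "hemisphere": hemi,
                    "lobe": members["lobe"].iloc[0],
                    "size_voxels": int(members["size_voxels"].sum()),
                    "region_class": members["region_class"].iloc[0],
                    "merge_group": "",
                }
            )
        )
    merged = pd.DataFrame(rows).reset_index(drop=True)
    return validate_node_table(merged), merge_map


def build_nodes(
    table: pd.DataFrame,
    min_size_voxels: int = 57,
    excluded_classes: set[str] | frozenset[str] = frozenset({"cerebellar"}),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Full node pipeline: validate, exclude, merge. Returns (nodes, merge_map)."""
    return apply_merges(apply_exclusions(table, min_size_voxels, excluded_classes))


def default_node_table() -> pd.DataFrame:
    """Synthetic 170-row parcellation table emulating a whole-brain atlas.

    Constructed so the standard pipeline (drop cerebellar regions, drop
    regions under 57 voxels unless mergeable, merge thalamic / nigral /
    tegmental subregions) yields exactly 105 nodes: 26 cerebellar rows,
    4 small unmergeable rows, 40 merge rows collapsing into 5 composite
    subcortical nodes (24 of them under the size threshold), and 100
    ordinary rows.  Region identities are synthetic; only the counts and
    lobe composition emulate a real atlas.
    """
    rows: list[dict] = []
    rid = 0

    def add(name, hemi, lobe, size, rclass, group=""):
        nonlocal rid
        rid += 1
        rows.append(
            {
                "region_id": str(rid),
                "name": name,
                "hemisphere": hemi,
                "lobe": lobe,
                "size_voxels": size,
                "region_class": rclass,
                "merge_group": group,
            }
        )

    # 100 ordinary cortical/subcortical regions that survive unchanged.
    lobe_plan = [
        ("frontal", 30),
        ("temporal", 16),
        ("parietal", 12),
        ("occipital", 12),
        ("cingulate", 10),
        ("subcortical", 12),
        ("insula", 2),
        ("other", 6),
    ]
    for lobe, n in lobe_plan:
        rclass = "subcortical" if lobe == "subcortical" else "cortical"
        for k in range(n):
            hemi = "left" if k % 2 == 0 else "right"
            add(f"{lobe}_{k + 1}", hemi, lobe, 200 + 13 * k, rclass)

    # 4 small regions without a merge group: excluded by the size rule.
    for k in range(4):
        add(f"tiny_{k + 1}", "left" if k % 2 == 0 else "right", "other", 30 + k, "cortical")

    # 40 merge rows -> 5 composite nodes; 24 rows below the 57-voxel threshold
    # (alternate thalamic subnuclei, all nigral subregions, both tegmental halves).
    for group, hemi, n_members in (
        ("THA_L", "left", 16),
        ("THA_R", "right", 16),
        ("SN_L", "left", 3),
        ("SN_R", "right", 3),
    ):
        for k in range(n_members):
            small = k % 2 == 0 or n_members <= 3
            size = 40 + k if small else 80 + 5 * k
            add(f"{group}_sub{k + 1}", hemi, "subcortical", size, "subcortical", group)
    add("VTA_sub1", "left", "subcortical", 45, "subcortical", "VTA")
    add("VTA_sub2", "right", "subcortical", 44, "subcortical", "VTA")

    # 26 cerebellar regions: excluded by class.
    for k in range(26):
        add(
            f"cerebellum_{k + 1}",
            "left" if k % 2 == 0 else "right",
            "other",
            300 + 7 * k,
            "cerebellar",
        )

    return validate_node_table(pd.DataFrame(rows))


def node_table_to_tsv_string(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
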
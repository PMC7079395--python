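"""Readers and writers for trees, state matrices, island maps and traces.

Formats are plain text: Newick for trees (internal node labels kept), TSV
for site-by-node state and methylation-fraction matrices, BED (0-based
half-open) for CpG-island maps, CSV for MCMC traces and JSON for ground
truth and run metadata.  Readers reject malformed input rather than
silently coercing it.

Also hosts the RRBS categorization rules: a site is unmethylated below 10%
methylated reads, methylated above 80%, partially methylated in between;
an island is called u or m when a strict majority of its sites is, else p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import IslandConfig, IWEvent, MethylationData
from .mcmc import Trace
from .model_core import MISSING, STATE_LABELS, GlobalParams
from .tree import Tree

__all__ = [
    "MISSING_TOKEN",
    "categorize_site",
    "categorize_fractions",
    "classify_island_state",
    "island_transition_summary",
    "IslandMap",
    "read_island_map",
    "write_island_map",
    "read_tree",
    "write_tree",
    "read_states",
    "write_states",
    "read_fractions",
    "write_trace",
    "read_trace",
    "write_ground_truth",
    "read_ground_truth",
]

MISSING_TOKEN = "-"
_CODE_OF = {"u": 0, "p": 1, "m": 2, MISSING_TOKEN: MISSING}
_LABEL_OF = {0: "u", 1: "p", 2: "m", MISSING: MISSING_TOKEN}


# ---------------------------------------------------------------------------
# RRBS categorization
# ---------------------------------------------------------------------------

def categorize_site(fraction) -> int:
    """Categorize a per-site methylated-read fraction into u/p/m codes.

    ``< 0.1`` is unmethylated, ``> 0.8`` methylated, the closed interval
    ``[0.1, 0.8]`` partially methylated; NaN/None stays missing.
    """
    if fraction is None or (isinstance(fraction, float) and np.isnan(fraction)):
        return MISSING
    fraction = float(fraction)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"methylation fraction must lie in [0, 1], got {fraction}")
    if fraction < 0.1:
        return 0
    if fraction > 0.8:
        return 2
    return 1


def categorize_fractions(fractions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`categorize_site` over an array (NaN -> missing)."""
    f = np.asarray(fractions, dtype=float)
    finite = ~np.isnan(f)
    if np.any((f[finite] < 0) | (f[finite] > 1)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    out = np.full(f.shape, MISSING, dtype=np.int8)
    out[finite & (f < 0.1)] = 0
    out[finite & (f >= 0.1) & (f <= 0.8)] = 1
    out[finite & (f > 0.8)] = 2
    return out


def classify_island_state(site_states) -> int:
    """Island-level state: u/m when a strict majority of sites is, else p."""
    s = np.asarray(site_states)
    s = s[s != MISSING]
    if s.size == 0:
        raise ValueError("cannot classify an island with all sites missing")
    if np.sum(s == 0) > s.size / 2:
        return 0
    if np.sum(s == 2) > s.size / 2:
        return 2
    return 1


def island_transition_summary(parent_states, child_states, island_offsets) -> pd.DataFrame:
    """3x3 table of island-state transitions along one branch.

    Rows are the parent-node island classifications, columns the child's.
    """
    offsets = np.asarray(island_offsets, dtype=np.int64)
    table = np.zeros((3, 3), dtype=np.int64)
    for i in range(len(offsets) - 1):
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        a = classify_island_state(np.asarray(parent_states)[sl])
        b = classify_island_state(np.asarray(child_states)[sl])
        table[a, b] += 1
    return pd.DataFrame(table, index=list(STATE_LABELS), columns=list(STATE_LABELS))


# ---------------------------------------------------------------------------
# Island maps (BED)
# ---------------------------------------------------------------------------

@dataclass
class IslandMap:
    """CpG-island intervals, BED convention (0-based, half-open), non-overlapping."""

    table: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self):
        required = {"chrom", "start", "end", "name"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"island map needs columns {sorted(required)}")
        by_chrom = self.table.sort_values(["chrom", "start"])
        for _, grp in by_chrom.groupby("chrom"):
            if np.any(grp["start"].values[1:] < grp["end"].values[:-1]):
                raise ValueError("islands must be non-overlapping")

    def assign(self, chrom: str, pos: int):
        """Island name containing position ``pos`` (0-based), or None."""
        t = self.table
        hit = t[(t["chrom"] == chrom) & (t["start"] <= pos) & (pos < t["end"])]
        if len(hit) == 0:
            return None
        return hit.iloc[0]["name"]


def read_island_map(path) -> IslandMap:
    try:
        table = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        )
    except Exception as exc:
        raise ValueError(f"malformed island BED file {path}: {exc}") from exc
    return IslandMap(table)


def write_island_map(path, island_map: IslandMap) -> None:
    island_map.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def write_tree(path, tree: Tree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# State matrices
# ---------------------------------------------------------------------------

def write_states(path, data: MethylationData, node_names) -> None:
    """TSV with columns ``island``, ``site`` and one u/p/m/- column per node."""
    names = data.island_names or [f"island{i}" for i in range(data.n_islands)]
    rows = {"island": [], "site": []}
    for i in range(data.n_islands):
        sl = data.island_slice(i)
        n = sl.stop - sl.start
        rows["island"].extend([names[i]] * n)
        rows["site"].extend(range(n))
    df = pd.DataFrame(rows)
    for j, name in enumerate(node_names):
        df[name] = [_LABEL_OF[int(c)] for c in data.states[j]]
    df.to_csv(path, sep="\t", index=False)


def read_states(path, node_names=None, island_map=None) -> MethylationData:
    """Read a states TSV back into a :class:`MethylationData`.

    Two layouts are accepted: an ``island`` column grouping contiguous sites,
    or ``chrom``/``pos`` columns plus an ``island_map`` assigning each site
    to an island (sites outside every island are an error).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "island" in df.columns:
        site_cols = [c for c in df.columns if c not in ("island", "site")]
        island_col = df["island"].tolist()
    elif {"chrom", "pos"}.issubset(df.columns):
        if island_map is None:
            raise ValueError("states file uses chrom/pos columns; an island map is required")
        site_cols = [c for c in df.columns if c not in ("chrom", "pos")]
        island_col = []
        for chrom, pos in zip(df["chrom"], df["pos"].astype(int)):
            name = island_map.assign(chrom, pos)
            if name is None:
                raise ValueError(f"site {chrom}:{pos} lies outside every island in the map")
            island_col.append(name)
    else:
        raise ValueError("states TSV needs an 'island' column or 'chrom'/'pos' columns")
    if node_names is not None:
        unknown = [c for c in site_cols if c not in node_names]
        missing = [n for n in node_names if n not in site_cols]
        if unknown or missing:
            raise ValueError(
                f"node columns do not match the tree: unknown {unknown}, missing {missing}"
            )
        site_cols = list(node_names)
    states = np.empty((len(site_cols), len(df)), dtype=np.int8)
    for j, col in enumerate(site_cols):
        try:
            states[j] = [_CODE_OF[v] for v in df[col]]
        except KeyError as exc:
            raise ValueError(
                f"invalid state token {exc.args[0]!r} in column {col!r} "
                f"(expected one of u/p/m/{MISSING_TOKEN})"
            ) from None
    # Contiguous island grouping.
    names, offsets = [], [0]
    for k, isl in enumerate(island_col):
        if not names or isl != names[-1]:
            if isl in names:
                raise ValueError(f"island {isl!r} appears in non-contiguous blocks")
            names.append(isl)
            if k > 0:
                offsets.append(k)
    offsets.append(len(island_col))
    return MethylationData(
        states, np.asarray(offsets), island_names=names, node_names=list(site_cols)
    )


def read_fractions(path) -> pd.DataFrame:
    """Per-site methylated-read fractions, same layout as the states TSV."""
    df = pd.read_csv(path, sep="\t")
    value_cols = [c for c in df.columns if c not in ("island", "site", "chrom", "pos")]
    for c in value_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        raw_missing = df[c].isna() | df[c].astype(str).isin(["NA", MISSING_TOKEN, ""])
        if (vals.isna() & ~raw_missing).any():
            raise ValueError(f"non-numeric methylation fraction in column {c!r}")
        df[c] = vals
    return df


# ---------------------------------------------------------------------------
# Traces and ground truth
# ---------------------------------------------------------------------------

def write_trace(path, trace: Trace, metadata_path=None) -> None:
    """Trace as CSV; run metadata (seed, priors, proposals) as a JSON sidecar."""
    trace.to_dataframe().to_csv(path, index=False)
    if metadata_path is not None:
        meta = {k: v for k, v in trace.meta.items() if _json_safe(v)}
        Path(metadata_path).write_text(json.dumps(meta, indent=2, default=_jsonify))


def _json_safe(v):
    try:
        json.dumps(v, default=_jsonify)
        return True
    except TypeError:
        return False


def _jsonify(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    raise TypeError(f"not JSON serializable: {type(v)}")


def read_trace(path) -> Trace:
    df = pd.read_csv(path)
    len_cols = [c for c in df.columns if c.startswith("log_length.")]
    names = [c.split(".", 1)[1] for c in len_cols]
    return Trace(
        step=df["step"].to_numpy(np.int64),
        loglik=df["loglik"].to_numpy(float),
        r=df["r"].to_numpy(float),
        alpha=df["alpha"].to_numpy(float),
        mu=df["mu"].to_numpy(float),
        branch_lengths=np.exp(df[len_cols].to_numpy(float)),
        iwe_counts=df[[f"iwe_count.{n}" for n in names]].to_numpy(np.int64),
        islands_with_iwe=df[[f"islands_with_iwe.{n}" for n in names]].to_numpy(np.int64),
        branch_names=names,
    )


def write_ground_truth(path, truth, tree: Tree) -> None:
    """Serialize a simulator GroundTruth bundle (full precision via repr floats)."""
    payload = {
        "theta": {"r": truth.theta.r, "alpha": truth.theta.alpha, "mu": truth.theta.mu},
        "branch_names": tree.branch_names(),
        "branch_lengths": [float(x) for x in truth.branch_lengths],
        "site_counts": [int(x) for x in truth.site_counts],
        "rate_values": [float(x) for x in truth.rate_values],
        "rate_categories": [int(x) for x in truth.rate_categories],
        "islands": [
            {
                "root_triple": [float(x) for x in c.root_triple],
                "events": [
                    {
                        "branch": tree.names[b],
                        "position": e.position,
                        "triple": [float(x) for x in e.triple],
                    }
                    for b, evs in sorted(c.events.items())
                    for e in evs
                ],
            }
            for c in truth.configs
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path, tree: Tree):
    from .simulator import GroundTruth

    payload = json.loads(Path(path).read_text())
    configs = []
    for isl in payload["islands"]:
        events = {}
        for ev in isl["events"]:
            b = tree.index_of(ev["branch"])
            events.setdefault(b, []).append(IWEvent(ev["position"], np.asarray(ev["triple"])))
        for b in events:
            events[b].sort(key=lambda e: e.position)
        configs.append(IslandConfig(np.asarray(isl["root_triple"]), events))
    th = payload["theta"]
    return GroundTruth(
        theta=GlobalParams(th["r"], th["alpha"], th["mu"]),
        branch_lengths=np.asarray(payload["branch_lengths"]),
        configs=configs,
        rate_values=np.asarray(payload["rate_values"]),
        rate_categories=np.asarray(payload["rate_categories"], dtype=np.int64),
        site_counts=np.asarray(payload["site_counts"], dtype=np.int64),
    )
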
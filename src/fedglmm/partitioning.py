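"""Data splitting for centralized / parallel use of the federated fitter.

Two strategies: a random split by the top-level grouping factor (patients),
and a clustering-based split for crossed patient/physician designs that
keeps physicians who share patients in the same subset, so the within-subset
correlation structure is preserved as much as a partition allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .model_core import ModelError, SiteData


@dataclass
class PartitionPlan:
    """Assignment of every encounter row to exactly one of m subsets."""

    m: int
    assignment: np.ndarray  # per-row subset index in [0, m)
    strategy: str
    seed: int

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min(initial=0) < 0 or (
            self.assignment.size and self.assignment.max() >= self.m
        ):
            raise ValueError("assignment indices out of range")
        counts = np.bincount(self.assignment, minlength=self.m)
        if np.any(counts == 0):
            raise ValueError("partition plan has an empty subset")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.m)

    def subsets(self, data: SiteData) -> list[SiteData]:
        """Materialize the subsets as independent SiteData objects."""
        if self.assignment.size != data.n_rows:
            raise ValueError("plan does not cover this dataset")
        out = []
        for i in range(self.m):
            tab = data.table.loc[self.assignment == i].reset_index(drop=True)
            out.append(SiteData(site_id=f"{data.site_id}::s{i}", table=tab))
        return out


def random_split(data: SiteData, m: int, seed: int) -> PartitionPlan:
    """Assign patients at random to m balanced subsets; all encounters of a
    patient stay together.  m = 1 returns the identity partition."""
    patients, codes = np.unique(data.table["patient_id"].to_numpy(), return_inverse=True)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > patients.size:
        raise ValueError(f"m={m} exceeds the {patients.size} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients.size)
    pat_subset = np.empty(patients.size, dtype=int)
    for i, chunk in enumerate(np.array_split(perm, m)):
        pat_subset[chunk] = i
    return PartitionPlan(m=m, assignment=pat_subset[codes],
                         strategy="random", seed=seed)


def build_sharing_graph(data: SiteData) -> nx.Graph:
    """Physicians' patient-sharing network.

    Nodes are physician ids with encounter counts as node weights; an edge
    joins two physicians iff at least one patient has encounters with both,
    weighted by the number of such distinct patients.
    """
    if "physician_id" not in data.table.columns:
        raise ModelError("physician_id column required for the sharing graph")
    tab = data.table
    g = nx.Graph()
    enc = tab.groupby("physician_id").size()
    for phys, n in enc.items():
        g.add_node(phys, encounters=int(n))
    seen = tab.groupby("patient_id")["physician_id"].agg(lambda s: frozenset(s))
    weights: dict[tuple, int] = {}
    for phys_set in seen:
        for a, b in combinations(sorted(phys_set), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    for (a, b), w in weights.items():
        g.add_edge(a, b, weight=w)
    return g


_BALANCE_CAP = 1.25  # x the even per-subset share of encounters


def cluster_split(data: SiteData, m: int, seed: int) -> PartitionPlan:
    """Greedy agglomeration on the patient-sharing network.

    Repeatedly merges the pair of physician clusters joined by the heaviest
    shared-patient weight, subject to a load cap of 1.25 x the even share of
    encounters per subset, until m clusters remain; leftover clusters are
    folded into the least-loaded bins.  Every encounter follows its
    physician, so patients seen by physicians in different subsets contribute
    rows to each.  Ties break on (weight, lexicographically smaller cluster
    id), making the plan deterministic; the seed is recorded as provenance.
    """
    graph = build_sharing_graph(data)
    physicians = sorted(graph.nodes)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(physicians):
        raise ValueError(f"m={m} exceeds the {len(physicians)} physicians")
    cap = _BALANCE_CAP * data.n_rows / m

    # cluster id = smallest member physician id (as str) for stable ties
    cid = {p: str(p) for p in physicians}
    members: dict[str, list] = {str(p): [p] for p in physicians}
    load = {str(p): graph.nodes[p]["encounters"] for p in physicians}
    wedge: dict[str, dict[str, float]] = {str(p): {} for p in physicians}
    for a, b, d in graph.edges(data=True):
        wedge[cid[a]][cid[b]] = wedge[cid[a]].get(cid[b], 0) + d["weight"]
        wedge[cid[b]][cid[a]] = wedge[cid[b]].get(cid[a], 0) + d["weight"]

    def merge(a: str, b: str) -> None:
        keep, gone = sorted((a, b))
        members[keep].extend(members.pop(gone))
        load[keep] += load.pop(gone)
        gw = wedge.pop(gone)
        wedge[keep].pop(gone, None)
        for c, w in gw.items():
            if c == keep:
                continue
            wedge[keep][c] = wedge[keep].get(c, 0) + w
            wedge[c].pop(gone, None)
            wedge[c][keep] = wedge[keep][c]

    while len(members) > m:
        best = None
        for a, nb in wedge.items():
            for b, w in nb.items():
                if a >= b or load[a] + load[b] > cap:
                    continue
                key = (-w, a, b)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        merge(best[1], best[2])

    # fold leftovers (singletons and capped-out clusters) into least-loaded bins
    while len(members) > m:
        order = sorted(members, key=lambda c: (load[c], c))
        smallest = order[0]
        target = min(
            (c for c in members if c != smallest), key=lambda c: (load[c], c)
        )
        merge(smallest, target)

    final = sorted(members, key=lambda c: (-load[c], c))
    phys_subset = {}
    for i, c in enumerate(final):
        for p in members[c]:
            phys_subset[p] = i
    assignment = data.table["physician_id"].map(phys_subset).to_numpy()
    return PartitionPlan(m=m, assignment=assignment, strategy="cluster", seed=seed)


def split_quality(plan: PartitionPlan, data: SiteData) -> dict:
    """How well a plan preserves the correlation structure.

    co_assignment: fraction of same-patient and same-physician encounter
    pairs that land in the same subset (1.0 for m=1).  balance_ratio: largest
    subset size over the even share.  Invariant to row order.
    """
    if plan.assignment.size != data.n_rows:
        raise ValueError("plan does not cover this dataset")
    tab = data.table
    cols = ["patient_id"] + (
        ["physician_id"] if "physician_id" in tab.columns else []
    )
    total = 0.0
    kept = 0.0
    for col in cols:
        df = pd.DataFrame({"g": tab[col].to_numpy(), "s": plan.assignment})
        sizes = df.groupby("g").size().to_numpy()
        total += float(np.sum(sizes * (sizes - 1) / 2))
        cell = df.groupby(["g", "s"]).size().to_numpy()
        kept += float(np.sum(cell * (cell - 1) / 2))
    counts = plan.counts
    return {
        "co_assignment": kept / total if total else 1.0,
        "balance_ratio": float(counts.max() / (data.n_rows / plan.m)),
        "subset_counts": counts.tolist(),
    }
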
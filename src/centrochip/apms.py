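"""Subcomplex inference from reciprocal affinity-purification/MS evidence.

Each purification of a YFP-tagged bait yields a list of detected proteins
with peptide counts; only proteins identified with at least two peptides
are considered. After filtering, the bait x protein detection matrix is
turned into a reciprocal-detection graph: two baits are linked when each
one's purification detects the other, and stable subcomplexes are read off
as the connected components. Proteins never used as baits (prey-only)
attach to a component when they are detected in at least a threshold
fraction of its baits' purifications. This formalises, as a reproducible
procedure, the kind of expert reading of a co-purification table that
produces subcomplex assignments such as KKT14-KKT15, KKT16-KKT17-KKT18 and
KKT6-KKT7-KKT8-KKT9-KKT10-KKT11-KKT12-KKT19 for the trypanosome
kinetochore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MIN_PEPTIDES = 2
SUPPORT_THRESHOLD = 0.75


def filter_evidence(evidence: pd.DataFrame, min_peptides: int = MIN_PEPTIDES) -> pd.DataFrame:
    """Drop evidence rows below the peptide-count threshold.

    ``evidence`` columns: bait, protein, peptides (non-negative ints).
    """
    required = {"bait", "protein", "peptides"}
    if not required.issubset(evidence.columns):
        raise ValueError(f"evidence table needs columns {sorted(required)}")
    if (evidence["peptides"] < 0).any():
        raise ValueError("peptide counts must be non-negative")
    return evidence[evidence["peptides"] >= min_peptides].reset_index(drop=True)


def build_matrix(filtered: pd.DataFrame) -> pd.DataFrame:
    """Boolean bait x protein co-purification matrix.

    Duplicate (bait, protein) rows are aggregated (max peptide count) with
    a warning. Columns are restricted to proteins passing the filter in at
    least one purification (which is every protein left in ``filtered``).
    """
    if filtered["bait"].nunique() == 0:
        raise ValueError("need at least one bait")
    dup = filtered.duplicated(subset=["bait", "protein"])
    if dup.any():
        warnings.warn(f"aggregating {int(dup.sum())} duplicate (bait, protein) rows")
        filtered = filtered.groupby(["bait", "protein"], as_index=False)["peptides"].max()
    mat = (
        filtered.assign(present=True)
        .pivot_table(index="bait", columns="protein", values="present",
                     aggfunc="any", fill_value=False)
        .astype(bool)
    )
    return mat


def apply_frequency_filter(matrix: pd.DataFrame, max_frequency: float = 0.8) -> pd.DataFrame:
    """Optionally drop contaminant-like prey columns detected in more than
    ``max_frequency`` of all purifications (baits themselves are kept)."""
    freq = matrix.mean(axis=0)
    keep = (freq <= max_frequency) | matrix.index.to_series().reindex(matrix.columns).notna()
    return matrix.loc[:, keep[matrix.columns]]


@dataclass
class SubcomplexCall:
    """Disjoint protein groups with per-group support scores.

    ``support[group_id][protein]`` is the fraction of that group's bait
    purifications detecting the protein.
    """

    groups: list[frozenset[str]]
    support: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def multi_protein_groups(self) -> list[frozenset[str]]:
        return [g for g in self.groups if len(g) >= 2]

    def group_of(self, protein: str) -> frozenset[str] | None:
        for g in self.groups:
            if protein in g:
                return g
        return None


def _bait_support(matrix: pd.DataFrame, comp: set[str], member: str) -> float:
    """Fraction of the component's bait purifications detecting ``member``."""
    comp_baits = sorted(comp)
    if member not in matrix.columns:
        return 0.0
    return float(matrix.loc[comp_baits, member].mean())


def _cluster_baits(matrix: pd.DataFrame, baits: list[str],
                   support_threshold: float) -> list[set[str]]:
    """Reciprocal-detection components over ``baits``, refined so every
    multi-member group satisfies the support invariant.

    A sporadic false-positive detection can forge one reciprocal edge and
    weld two real subcomplexes together; inside such a chimeric component
    most members are detected by only a minority of the baits. Members
    whose support falls below the threshold are therefore peeled off
    (lowest support first, ties alphabetical) and re-clustered among
    themselves, which restores the underlying blocks.
    """
    if not baits:
        return []
    g = nx.Graph()
    g.add_nodes_from(baits)
    for i, a in enumerate(baits):
        for b in baits[i + 1:]:
            if (b in matrix.columns and a in matrix.columns
                    and matrix.at[a, b] and matrix.at[b, a]):
                g.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(g)]

    final: list[set[str]] = []
    leftovers: list[str] = []
    for comp in components:
        comp = set(comp)
        while len(comp) >= 2:
            supports = {m: _bait_support(matrix, comp, m) for m in comp}
            weakest = min(sorted(comp), key=lambda m: supports[m])
            if supports[weakest] >= support_threshold:
                break
            comp.remove(weakest)
            leftovers.append(weakest)
        final.append(comp)
    if leftovers:
        final.extend(_cluster_baits(matrix, sorted(leftovers), support_threshold))
    return [c for c in final if c]


def deduce_subcomplexes(
    matrix: pd.DataFrame, support_threshold: float = SUPPORT_THRESHOLD
) -> SubcomplexCall:
    """Connected components of the reciprocal-detection graph.

    Baits a and b are joined when a's purification detects b AND b's
    detects a; components are refined until every multi-member group has
    all-member support >= ``support_threshold`` (see
    :func:`_cluster_baits`). A prey-only protein joins the component in
    which it is detected by the largest fraction of bait purifications,
    provided that fraction reaches the threshold; otherwise it stays a
    singleton. Output is deterministic: groups are sorted by their
    smallest member.
    """
    baits = list(matrix.index)
    proteins = list(matrix.columns)
    components = _cluster_baits(matrix, baits, support_threshold)

    prey_only = [p for p in proteins if p not in set(baits)]
    support: dict[int, dict[str, float]] = {
        ci: {p: _bait_support(matrix, comp, p) for p in proteins}
        for ci, comp in enumerate(components)
    }
    for p in prey_only:
        scores = [(support[ci].get(p, 0.0), -len(components[ci]), -ci)
                  for ci in range(len(components))]
        if scores:
            best_score, _, neg_ci = max(scores)
            best_ci = -neg_ci
        else:
            best_score, best_ci = 0.0, -1
        if best_score >= support_threshold and best_ci >= 0:
            components[best_ci].add(p)
        else:
            components.append({p})

    groups = sorted((frozenset(c) for c in components), key=lambda s: sorted(s)[0])
    return SubcomplexCall(groups=list(groups), support=support)


class CopurificationModel:
    """statsmodels-style front end: evidence table in, fitted groups out."""

    def __init__(self, evidence: pd.DataFrame, min_peptides: int = MIN_PEPTIDES):
        self.evidence = evidence
        self.min_peptides = min_peptides

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CopurificationModel":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def fit(self, support_threshold: float = SUPPORT_THRESHOLD,
            frequency_filter: float | None = None) -> "SubcomplexResults":
        filtered = filter_evidence(self.evidence, self.min_peptides)
        matrix = build_matrix(filtered)
        if frequency_filter is not None:
            matrix = apply_frequency_filter(matrix, frequency_filter)
        call = deduce_subcomplexes(matrix, support_threshold)
        return SubcomplexResults(self, matrix, call)


class SubcomplexResults:
    def __init__(self, model: CopurificationModel, matrix: pd.DataFrame,
                 call: SubcomplexCall):
        self.model = model
        self.matrix = matrix
        self.call = call

    @property
    def groups(self) -> list[frozenset[str]]:
        return self.call.groups

    def summary(self) -> str:
        lines = [
            "AP-MS subcomplex inference",
            "=" * 60,
            f"evidence rows: {len(self.model.evidence)} "
            f"(min peptides: {self.model.min_peptides})",
            f"baits: {self.matrix.shape[0]}; proteins: {self.matrix.shape[1]}",
            f"groups: {len(self.call.groups)} "
            f"({len(self.call.multi_protein_groups)} with >= 2 members)",
        ]
        for g in self.call.groups:
            members = ", ".join(sorted(g))
            lines.append(f"  [{len(g)}] {members}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein\tgroup\n")
            for gi, g in enumerate(self.call.groups):
                for p in sorted(g):
                    fh.write(f"{p}\t{gi}\n")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def kkt_reference_evidence(noise_rate: float = 0.0, rng_seed: int = 0,
                           peptides: int = 5) -> pd.DataFrame:
    """Synthetic noise-free (or perturbed) evidence table encoding the
    trypanosome kinetochore subcomplex membership: each bait detects
    itself and its subcomplex partners. ``noise_rate`` adds random
    false-positive detections between groups.
    """
    groups = [
        ["KKT14", "KKT15"],
        ["KKT16", "KKT17", "KKT18"],
        ["KKT6", "KKT7", "KKT8", "KKT9", "KKT10", "KKT11", "KKT12", "KKT19"],
        ["KKT1"], ["KKT2"], ["KKT3"], ["KKT4"], ["KKT5"], ["KKT13"],
    ]
    rows = []
    all_proteins = [p for g in groups for p in g]
    for g in groups:
        for bait in g:
            for prey in g:
                rows.append({"bait": bait, "protein": prey, "peptides": peptides})
    df = pd.DataFrame(rows)
    if noise_rate > 0:
        rng = np.random.default_rng(rng_seed)
        present = set(zip(df["bait"], df["protein"]))
        extra = []
        for bait in all_proteins:
            for prey in all_proteins:
                if (bait, prey) in present:
                    continue
                if rng.random() < noise_rate:
                    extra.append({"bait": bait, "protein": prey, "peptides": peptides})
        if extra:
            df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df.sort_values(["bait", "protein"], ignore_index=True)
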
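"""Clone-cutoff derivation, clone grouping and nomenclature reports.

The collection's bespoke procedure: because clonally propagated trees are
never 100% identical under multiplexed genotyping, an objective cutoff is
derived from the data itself. Pairs of identically named (or
known-synonymous) samples that are sisters in the NJ tree, plus tight
clades holding at least two same-named samples with at most ``max_extra``
others, form *seed groups*; the maximum within-seed-group pairwise
p-distance becomes the cutoff; single-linkage clustering at that cutoff
partitions the collection into clonal groups and singletons. Groups are
then read against the cultivar names to report synonyms (one group,
several names), homonyms (one name, several groups) and candidate names
for unnamed samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import DistanceMatrix, EmptyInputError, ParameterError

from . import njtree


@dataclass
class SeedGroup:
    """>= 2 same-named (or known-synonym) samples in one tight clade,
    with at most ``max_extra`` other samples riding along."""

    members: tuple
    anchor: str
    max_distance: float


@dataclass
class CloneGrouping:
    """Partition of the collection at a distance cutoff: clonal groups
    (size >= 2) plus singletons."""

    cutoff: float
    groups: list
    singletons: list

    def all_samples(self) -> list:
        out = [s for g in self.groups for s in g]
        out.extend(self.singletons)
        return out

    def group_of(self) -> dict:
        out = {}
        for gi, g in enumerate(self.groups):
            for s in g:
                out[s] = gi
        return out


@dataclass
class SynonymyReport:
    synonym_sets: list = field(default_factory=list)   # (group_idx, names)
    homonyms: dict = field(default_factory=dict)       # name -> n locations
    unknown_suggestions: dict = field(default_factory=dict)


def _name_keys(samples: pd.DataFrame) -> dict:
    """sample_id -> matching key: the synonym group when given, else the
    normalised cultivar name; unknown samples map to None."""
    keys = {}
    for row in samples.itertuples(index=False):
        if getattr(row, "is_unknown", False) or not row.name_key:
            keys[row.sample_id] = None
        elif getattr(row, "synonym_group", ""):
            keys[row.sample_id] = f"syn:{row.synonym_group}"
        else:
            keys[row.sample_id] = row.name_key
    return keys


def find_same_name_sister_pairs(tree, samples: pd.DataFrame) -> list:
    """Cherries (two-tip clades) whose tips share a cultivar name or a
    known synonym group."""
    keys = _name_keys(samples)
    pairs = []
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            a, b = (c.taxon.label for c in children)
            if keys.get(a) is not None and keys.get(a) == keys.get(b):
                pairs.append(tuple(sorted((a, b))))
    return sorted(set(pairs))


def find_seed_groups(
    tree, samples: pd.DataFrame, D: DistanceMatrix, max_extra: int = 2
) -> list:
    """Seed groups: tight clades with >= 2 same-named tips and
    <= ``max_extra`` extra tips. Sister pairs are always included as
    size-2 groups; beyond those, the qualifying clade chosen per name
    maximises the same-named member count and then minimises the
    outsiders. Raises when nothing qualifies (the caller should then
    supply a manual cutoff)."""
    keys = _name_keys(samples)
    idx = {lab: i for i, lab in enumerate(D.labels)}

    def max_internal(members) -> float:
        ii = [idx[m] for m in members]
        sub = D.values[np.ix_(ii, ii)]
        return float(sub.max())

    candidates: dict[str, list] = {}
    clades = [tuple(sorted(p)) for p in
              find_same_name_sister_pairs(tree, samples)]
    clades.extend(njtree.tight_clades(tree))
    for clade in clades:
        counts: dict[str, int] = {}
        for tip in clade:
            k = keys.get(tip)
            if k is not None:
                counts[k] = counts.get(k, 0) + 1
        for k, c in counts.items():
            if c >= 2 and len(clade) - c <= max_extra:
                candidates.setdefault(k, []).append(set(clade))

    sister_pairs = {tuple(sorted(p))
                    for p in find_same_name_sister_pairs(tree, samples)}
    groups = []
    seen = set()

    def _add(k, members):
        if (k, members) in seen:
            return
        seen.add((k, members))
        groups.append(SeedGroup(members=members, anchor=k,
                                max_distance=max_internal(members)))

    def _n_anchor(s, k):
        return sum(1 for tip in s if keys.get(tip) == k)

    for k, clade_sets in candidates.items():
        # sister pairs always seed a group; beyond that, the expansion
        # chosen per anchor is the qualifying clade with the most
        # same-named tips and, among those, the fewest outsiders —
        # the tightest group holding the name's cluster
        for s in clade_sets:
            members = tuple(sorted(s))
            if members in sister_pairs:
                _add(k, members)
        best = min(
            clade_sets,
            key=lambda s: (-_n_anchor(s, k), len(s) - _n_anchor(s, k),
                           max_internal(tuple(s)), tuple(sorted(s))),
        )
        _add(k, tuple(sorted(best)))
    if not groups:
        raise EmptyInputError(
            "no seed groups found (no tight clade holds two same-named "
            "samples); supply a manual clone-distance cutoff instead"
        )
    return sorted(groups, key=lambda g: (g.anchor, g.members))


def derive_cutoff(seed_groups) -> float:
    """The clone-distance cutoff: the maximum over seed groups of the
    maximum within-group pairwise distance. Accepts
    :class:`SeedGroup` objects or plain per-group maxima."""
    maxima = [
        float(getattr(g, "max_distance", g)) for g in seed_groups
    ]
    if not maxima:
        raise EmptyInputError("cannot derive a cutoff from zero seed groups")
    return max(maxima)


def clone_groups(D: DistanceMatrix, cutoff: float) -> CloneGrouping:
    """Single-linkage partition at the cutoff: connected components of
    the graph with an edge wherever d(i, j) <= cutoff."""
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    n = D.n
    adj = csr_matrix((D.values <= cutoff) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    groups, singletons = [], []
    for c in range(n_comp):
        members = sorted(D.labels[i] for i in np.flatnonzero(labels == c))
        if len(members) >= 2:
            groups.append(members)
        else:
            singletons.extend(members)
    groups.sort(key=lambda g: (-len(g), g))
    return CloneGrouping(cutoff=float(cutoff), groups=groups,
                         singletons=sorted(singletons))


def grouping_summary(grouping: CloneGrouping) -> dict:
    """Bookkeeping of a clone partition: group count, clonal-sample
    count, largest group, and distinct genotypes
    (groups + singletons)."""
    sizes = [len(g) for g in grouping.groups]
    return {
        "n_groups": len(grouping.groups),
        "n_clonal_samples": int(sum(sizes)),
        "n_singletons": len(grouping.singletons),
        "max_group_size": max(sizes) if sizes else 0,
        "n_distinct_genotypes": len(grouping.groups) + len(grouping.singletons),
        "n_samples": int(sum(sizes)) + len(grouping.singletons),
    }


def classify_nomenclature(
    grouping: CloneGrouping, samples: pd.DataFrame
) -> SynonymyReport:
    """Read a clone partition against cultivar names.

    A group carrying >= 2 distinct names is a synonym set; a name spread
    over >= 2 groups/singletons is a homonym; an unnamed sample grouped
    with exactly one distinct name gets that name suggested (>= 2 names:
    ambiguous; alone: none).
    """
    info = samples.set_index("sample_id")
    report = SynonymyReport()

    def name_of(s):
        return None if bool(info.at[s, "is_unknown"]) else str(
            info.at[s, "cultivar_name"]
        )

    for gi, group in enumerate(grouping.groups):
        names = sorted({n for n in (name_of(s) for s in group) if n})
        if len(names) >= 2:
            report.synonym_sets.append((gi, names))
        for s in group:
            if name_of(s) is None:
                if len(names) == 1:
                    report.unknown_suggestions[s] = names[0]
                elif len(names) >= 2:
                    report.unknown_suggestions[s] = "ambiguous"
                else:
                    report.unknown_suggestions[s] = None
    for s in grouping.singletons:
        if name_of(s) is None:
            report.unknown_suggestions[s] = None

    # homonyms: a name appearing in >= 2 distinct locations
    # (group index or its own singleton)
    locations: dict[str, set] = {}
    for gi, group in enumerate(grouping.groups):
        for s in group:
            n = name_of(s)
            if n:
                locations.setdefault(n, set()).add(("group", gi))
    for s in grouping.singletons:
        n = name_of(s)
        if n:
            locations.setdefault(n, set()).add(("singleton", s))
    report.homonyms = {
        n: len(locs) for n, locs in sorted(locations.items()) if len(locs) >= 2
    }
    return report


def read_clone_groups_tsv(path) -> CloneGrouping:
    """Read a clone partition from TSV (columns ``group_id``,
    ``sample_id``; a ``.`` group id marks a singleton)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"group_id", "sample_id"}.issubset(df.columns):
        raise ParameterError("clone-group TSV needs group_id and sample_id")
    if df["sample_id"].duplicated().any():
        raise ParameterError("a sample may appear in only one group")
    groups = []
    singles = list(df.loc[df["group_id"] == ".", "sample_id"])
    for gid, sub in df[df["group_id"] != "."].groupby("group_id", sort=True):
        members = sorted(sub["sample_id"])
        if len(members) == 1:
            singles.extend(members)
        else:
            groups.append(members)
    groups.sort(key=lambda g: (-len(g), g))
    return CloneGrouping(cutoff=float("nan"), groups=groups,
                         singletons=sorted(singles))


def write_clone_groups_tsv(grouping: CloneGrouping, path) -> None:
    rows = []
    for gi, group in enumerate(grouping.groups, start=1):
        rows.extend({"group_id": f"G{gi:02d}", "sample_id": s} for s in group)
    rows.extend({"group_id": ".", "sample_id": s}
                for s in grouping.singletons)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
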
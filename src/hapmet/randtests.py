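"""Network-based permutation tests for trait structure.

Two statistics are computed on a rooted haplotype network with one trait
value per individual:

* ``T1(k)`` — the sum, over all unordered pairs of individuals whose
  haplotypes are at most k mutational steps apart in the network, of the
  absolute difference in metabolic rate.  Small values mean network
  neighbours have similar rates; k=0 restricts to individuals sharing a
  haplotype.
* ``T2`` — the sum, over all directed edges (u, v) of the network (edges
  point away from the root; inferred memberless nodes are contracted first),
  of mean rate at v minus mean rate at u.  Large values mean rates increase
  moving away from the putative ancestral haplotype.

Significance is assessed by shuffling the trait values across individuals
without replacement, keeping the network fixed.  By default T1 uses the
lower tail (similarity) and T2 the upper tail (directional increase), with
add-one smoothing; flags recover the plain-proportion, upper-tail
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InputError
from .io import TraitTable
from .network import RootedNetwork

__all__ = ["PermutationResult", "t1_statistic", "t2_statistic", "permutation_test"]


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null sample and p-value."""

    statistic_name: str
    k: int | None
    observed: float
    null_values: tuple[float, ...] = field(repr=False)
    n_perm: int
    tail: str
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "k": self.k,
            "observed": self.observed,
            "null_values": list(self.null_values),
            "n_perm": self.n_perm,
            "tail": self.tail,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def _individuals_and_rates(
    rooted: RootedNetwork, traits: TraitTable
) -> tuple[list[str], np.ndarray]:
    mapping = rooted.network.individual_to_haplotype
    ids = sorted(mapping)
    rates = traits.rates()
    missing = [i for i in ids if i not in rates]
    if missing:
        raise InputError(f"individuals missing from trait table: {missing}")
    extra = [i for i in rates if i not in mapping]
    if extra:
        raise InputError(f"trait individuals missing from network: {extra}")
    return ids, np.array([rates[i] for i in ids], dtype=float)


def _t1_pair_indices(
    rooted: RootedNetwork, ids: list[str], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the unordered individual pairs with network
    distance <= k between their haplotypes."""
    graph = rooted.network.graph
    mapping = rooted.network.individual_to_haplotype
    hap_dist = dict(nx.all_pairs_shortest_path_length(graph, cutoff=k))
    ii, jj = [], []
    for a in range(len(ids)):
        ha = mapping[ids[a]]
        for b in range(a + 1, len(ids)):
            hb = mapping[ids[b]]
            if hb in hap_dist.get(ha, {}):
                ii.append(a)
                jj.append(b)
    return np.array(ii, dtype=int), np.array(jj, dtype=int)


def _t2_linear_form(
    rooted: RootedNetwork, ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """T2 is linear in the trait vector m: T2 = w @ (M @ m).

    M averages member traits per observed node; w_n = indegree(n) -
    outdegree(n) in the contracted directed network, since each directed
    edge (u, v) contributes +mean(v) - mean(u).
    """
    contracted = rooted.contracted_digraph()
    nodes = sorted(contracted.nodes())
    idx = {ind: a for a, ind in enumerate(ids)}
    members = {
        h.haplotype_id: h.members for h in rooted.network.haplotypes
    }
    M = np.zeros((len(nodes), len(ids)))
    for r, node in enumerate(nodes):
        mem = members[node]
        for ind in mem:
            M[r, idx[ind]] = 1.0 / len(mem)
    w = np.array(
        [
            contracted.in_degree(node) - contracted.out_degree(node)
            for node in nodes
        ],
        dtype=float,
    )
    return w, M


def t1_statistic(rooted: RootedNetwork, traits: TraitTable, k: int) -> float:
    """T1(k): summed |rate(i) - rate(j)| over unordered pairs within k
    mutational steps (0 = same haplotype)."""
    if k < 0:
        raise InputError(f"k must be >= 0, got {k}")
    ids, m = _individuals_and_rates(rooted, traits)
    ii, jj = _t1_pair_indices(rooted, ids, k)
    return float(np.abs(m[ii] - m[jj]).sum())


def t2_statistic(rooted: RootedNetwork, traits: TraitTable) -> float:
    """T2: summed (mean rate at child - mean rate at parent) over directed
    edges of the contracted network."""
    ids, m = _individuals_and_rates(rooted, traits)
    w, M = _t2_linear_form(rooted, ids)
    if len(rooted.network.haplotypes) == 1:
        warnings.warn("single-haplotype network: T2 is identically 0")
        return 0.0
    return float(w @ (M @ m))


def permutation_test(
    stat: str,
    rooted: RootedNetwork,
    traits: TraitTable,
    k: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    literal_upper_tail: bool = False,
    plain_proportion: bool = False,
) -> PermutationResult:
    """Permutation test for T1(k) or T2 by shuffling traits across
    individuals.

    ``literal_upper_tail`` forces the upper tail for both statistics (the
    single "proportion higher" rule); otherwise T1 uses the lower tail and
    T2 the upper.  ``plain_proportion`` drops the add-one smoothing.  Ties
    between null and observed count as at least as extreme.
    """
    stat = stat.upper()
    if stat not in ("T1", "T2"):
        raise InputError(f"unknown statistic {stat!r}; expected T1 or T2")
    if n_perm < 1:
        raise InputError(f"n_perm must be >= 1, got {n_perm}")
    if stat == "T2" and k is not None:
        raise InputError("k applies only to T1")
    if stat == "T1" and k is None:
        raise InputError("T1 requires k")

    ids, m = _individuals_and_rates(rooted, traits)
    if stat == "T1":
        ii, jj = _t1_pair_indices(rooted, ids, k)

        def evaluate(vec: np.ndarray) -> float:
            return float(np.abs(vec[ii] - vec[jj]).sum())

        tail = "lower"
    else:
        w, M = _t2_linear_form(rooted, ids)
        wM = w @ M

        def evaluate(vec: np.ndarray) -> float:
            return float(wM @ vec)

        tail = "upper"
    if literal_upper_tail:
        tail = "upper"

    observed = evaluate(m)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = evaluate(rng.permutation(m))

    if tail == "lower":
        count = int(np.sum(null <= observed))
    else:
        count = int(np.sum(null >= observed))
    if plain_proportion:
        p_value = count / n_perm
    else:
        p_value = (1 + count) / (n_perm + 1)

    return PermutationResult(
        statistic_name=stat,
        k=k,
        observed=observed,
        null_values=tuple(null.tolist()),
        n_perm=n_perm,
        tail=tail,
        p_value=p_value,
        seed=seed,
    )
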
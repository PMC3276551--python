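"""PDZ domain-mediated interaction network (PDZNet) construction and analysis.

PPI edge lists are integrated into one undirected network, interactions
touching a PDZ protein are extracted and annotated with the partner's
C-terminal tetrapeptide and predicted binding score, and two filters drop
candidate edges better explained by domain-domain contacts or by other
peptide-binding domains (SH3, WW, ...) when the PDZ score falls below the
cutoff set by the lowest experimentally confirmed score. One-mode
projections connect PDZ proteins sharing a ligand (PPN) or ligands sharing
a PDZ protein (PLN); paralog fractions among partner-sharing pairs
quantify how much of the network's redundancy gene duplication explains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class PpiEdge:
    """One undirected PPI record; the pair is stored in sorted order."""

    protein_a: str
    protein_b: str
    evidence: frozenset = frozenset()
    direct_experimental: bool = True

    def __post_init__(self) -> None:
        a, b = sorted((self.protein_a, self.protein_b))
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        object.__setattr__(self, "evidence", frozenset(self.evidence))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def integrate_ppi(edge_lists: list[list[PpiEdge]]) -> tuple[list[PpiEdge], int]:
    """Union edge lists into one deduplicated, direct-evidence-only set.

    Self-loops and edges lacking direct experimental support are dropped;
    evidence tags of duplicate pairs are unioned. Returns the edges plus
    the number of rows skipped (self-loops / unsupported).
    """
    merged: dict[tuple[str, str], set] = {}
    flags: dict[tuple[str, str], bool] = {}
    skipped = 0
    for edges in edge_lists:
        for e in edges:
            if e.protein_a == e.protein_b:
                skipped += 1
                continue
            merged.setdefault(e.pair, set()).update(e.evidence)
            flags[e.pair] = flags.get(e.pair, False) or e.direct_experimental
    out = []
    for pair in sorted(merged):
        if not flags[pair]:
            skipped += 1
            continue
        out.append(PpiEdge(*pair, frozenset(merged[pair]), True))
    return out, skipped


@dataclass
class PdzNetwork:
    """Bipartite network of PDZ proteins vs ligand proteins.

    Backed by a networkx Graph with node attribute ``is_pdz`` and edge
    attributes ``score`` (predicted binding score), ``motif`` (ligand
    C-terminal tetrapeptide) and ``evidence``. A protein that is itself a
    PDZ protein may appear on the ligand side of another PDZ protein; the
    bipartition is by role within each edge (``pdz``/``ligand`` endpoint
    attributes), with ``is_pdz`` marking PDZ-protein nodes.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_interaction(
        self,
        pdz: str,
        ligand: str,
        score: float = np.nan,
        motif: str = "",
        evidence=(),
        domain_id: str | None = None,
    ) -> None:
        self.graph.add_node(pdz, is_pdz=True)
        self.graph.add_node(ligand, **{"is_pdz": self.graph.nodes.get(ligand, {}).get("is_pdz", False)})
        if self.graph.has_edge(pdz, ligand):
            data = self.graph.edges[pdz, ligand]
            data["evidence"] = frozenset(data.get("evidence", frozenset())) | frozenset(evidence)
            if domain_id:
                data.setdefault("domains", set()).add(domain_id)
            if np.isfinite(score):
                data["score"] = score
            return
        self.graph.add_edge(
            pdz,
            ligand,
            pdz=pdz,
            ligand=ligand,
            score=score,
            motif=motif,
            evidence=frozenset(evidence),
            domains={domain_id} if domain_id else set(),
        )

    @property
    def pdz_proteins(self) -> set[str]:
        return {d["pdz"] for _, _, d in self.graph.edges(data=True)}

    @property
    def ligands(self) -> set[str]:
        return {d["ligand"] for _, _, d in self.graph.edges(data=True)}

    def edges(self):
        return [
            (d["pdz"], d["ligand"], d) for _, _, d in self.graph.edges(data=True)
        ]

    def partners_of(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node)) if node in self.graph else set()


def extract_pdz_mediated(
    edges: list[PpiEdge],
    pdz_proteins: set[str],
    ctermini: dict[str, str] | None = None,
) -> list[dict]:
    """Keep edges with at least one PDZ endpoint; annotate ligand motifs.

    Each retained edge becomes a candidate dict with ``pdz``/``ligand``
    roles (both orientations when both endpoints are PDZ proteins) and the
    ligand's C-terminal tetrapeptide when its sequence is known.
    """
    ctermini = ctermini or {}
    out = []
    for e in edges:
        for pdz, lig in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            if pdz in pdz_proteins:
                seq = ctermini.get(lig, "")
                out.append(
                    {
                        "pdz": pdz,
                        "ligand": lig,
                        "motif": seq.upper()[-4:] if len(seq) >= 4 else "",
                        "evidence": e.evidence,
                    }
                )
    return out


def filter_domain_domain(
    candidates: list[dict],
    ddi_catalog: set[tuple[str, str]],
    domain_annotations: dict[str, set[str]],
    scores: dict[tuple[str, str], float],
    cutoff: float,
) -> tuple[list[dict], list[dict], list[str]]:
    """Drop candidates explained by a catalogued non-PDZ domain-domain contact.

    A candidate is removed only when some non-PDZ domain pair across the
    two proteins appears in the DDI catalog *and* its PDZ binding score is
    below ``cutoff`` — catalogued DDIs enrich only among low-scoring PDZ
    interactions, so high-scoring edges are kept. Candidates whose
    proteins lack domain annotation are kept with a warning.
    """
    kept, removed, warnings = [], [], []
    catalog = {tuple(sorted(p)) for p in ddi_catalog}
    for c in candidates:
        pdz, lig = c["pdz"], c["ligand"]
        if pdz not in domain_annotations or lig not in domain_annotations:
            warnings.append(f"missing domain annotation for edge {pdz}-{lig}; kept")
            kept.append(c)
            continue
        doms_a = {d for d in domain_annotations[pdz] if d != "PDZ"}
        doms_b = {d for d in domain_annotations[lig] if d != "PDZ"}
        has_ddi = any(
            tuple(sorted((da, db))) in catalog
            for da in doms_a
            for db in doms_b
        )
        score = scores.get((pdz, lig), np.nan)
        low = (not np.isfinite(score)) or score < cutoff
        if has_ddi and low:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed, warnings


def confirmed_score_cutoff(confirmed_scores: list[float]) -> float:
    """Cutoff = lowest binding score among experimentally confirmed pairs."""
    if not confirmed_scores:
        raise NetworkError("no confirmed interaction scores to set a cutoff")
    return min(confirmed_scores)


def filter_other_motif_domains(
    candidates: list[dict],
    other_motif_flags: dict[tuple[str, str], bool],
    scores: dict[tuple[str, str], float],
    confirmed_scores: list[float],
) -> tuple[list[dict], list[dict], float]:
    """Drop candidates attributable to other peptide-binding domains.

    An edge flagged as carrying another peptide-binding-domain motif (SH3,
    WW, ...) is removed when its PDZ binding score falls below the lowest
    experimentally confirmed score.
    """
    cutoff = confirmed_score_cutoff(confirmed_scores)
    kept, removed = [], []
    for c in candidates:
        key = (c["pdz"], c["ligand"])
        flagged = other_motif_flags.get(key, False)
        score = scores.get(key, np.nan)
        if flagged and np.isfinite(score) and score < cutoff:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed, cutoff


def build_pdznet(candidates: list[dict], scores: dict | None = None) -> PdzNetwork:
    """Assemble filtered candidates into the bipartite network."""
    scores = scores or {}
    net = PdzNetwork()
    for c in candidates:
        net.add_interaction(
            c["pdz"],
            c["ligand"],
            score=scores.get((c["pdz"], c["ligand"]), c.get("score", np.nan)),
            motif=c.get("motif", ""),
            evidence=c.get("evidence", ()),
            domain_id=c.get("domain_id"),
        )
    return net


def project_bipartite(net: PdzNetwork, mode: str) -> nx.Graph:
    """One-mode projection: PPN (mode='ppn') or PLN (mode='pln').

    Two same-side nodes are connected iff they share at least one partner;
    the edge weight is the number of shared partners.
    """
    if mode.lower() not in ("ppn", "pln"):
        raise NetworkError("mode must be 'ppn' or 'pln'")
    side_of_edge = "pdz" if mode.lower() == "ppn" else "ligand"
    other = "ligand" if side_of_edge == "pdz" else "pdz"
    partners: dict[str, set[str]] = {}
    for _, _, d in net.graph.edges(data=True):
        partners.setdefault(d[side_of_edge], set()).add(d[other])
    proj = nx.Graph()
    proj.add_nodes_from(partners)
    for u, v in itertools.combinations(sorted(partners), 2):
        shared = partners[u] & partners[v]
        if shared:
            proj.add_edge(u, v, weight=len(shared))
    return proj


def network_summary(net: PdzNetwork) -> dict:
    """Node/edge counts, mean degrees per side, largest-component fraction."""
    pdz, lig = net.pdz_proteins, net.ligands
    n_edges = net.graph.number_of_edges()
    summary = {
        "n_pdz_proteins": len(pdz),
        "n_ligands": len(lig),
        "n_interactions": n_edges,
        "mean_pdz_degree": (n_edges / len(pdz)) if pdz else 0.0,
        "mean_ligand_degree": (n_edges / len(lig)) if lig else 0.0,
        "largest_component_fraction": 0.0,
    }
    if net.graph.number_of_nodes():
        biggest = max(nx.connected_components(net.graph), key=len)
        summary["largest_component_fraction"] = len(biggest) / net.graph.number_of_nodes()
    return summary


def _sharing_pairs(net: PdzNetwork, side: str) -> list[tuple[str, str]]:
    proj = project_bipartite(net, "ppn" if side == "pdz" else "pln")
    return [tuple(sorted(e)) for e in proj.edges()]


def paralog_fraction(
    net: PdzNetwork,
    paralog_pairs: set[tuple[str, str]],
    side: str,
) -> tuple[float, list[tuple[str, str]]]:
    """Fraction of partner-sharing pairs on one side that are paralogous.

    ``side`` is 'pdz' or 'ligand'. Raises if fewer than two pairs share a
    partner (fraction undefined).
    """
    if side not in ("pdz", "ligand"):
        raise NetworkError("side must be 'pdz' or 'ligand'")
    pairs = _sharing_pairs(net, side)
    if len(pairs) < 2:
        raise NetworkError(f"fewer than 2 partner-sharing pairs on the {side} side")
    paralogs = {tuple(sorted(p)) for p in paralog_pairs}
    hits = [p for p in pairs if p in paralogs]
    return len(hits) / len(pairs), pairs


def per_node_paralog_fractions(
    net: PdzNetwork, paralog_pairs: set[tuple[str, str]], side: str
) -> dict[str, float]:
    """For each node, the paralogous share of its partner-sharing pairs."""
    paralogs = {tuple(sorted(p)) for p in paralog_pairs}
    counts: dict[str, list[int]] = {}
    for u, v in _sharing_pairs(net, side):
        hit = (u, v) in paralogs
        for node in (u, v):
            tot_hit = counts.setdefault(node, [0, 0])
            tot_hit[0] += 1
            tot_hit[1] += int(hit)
    return {n: h / t for n, (t, h) in counts.items()}


def compare_paralog_fractions(
    net: PdzNetwork, paralog_pairs: set[tuple[str, str]]
) -> dict:
    """Wilcoxon rank-sum comparison of per-node paralog fractions, PDZ vs ligand.

    The exact null distribution is used for small samples (both sides
    <= 20 nodes), the normal approximation with continuity correction
    otherwise.
    """
    pdz = list(per_node_paralog_fractions(net, paralog_pairs, "pdz").values())
    lig = list(per_node_paralog_fractions(net, paralog_pairs, "ligand").values())
    if not pdz or not lig:
        raise NetworkError("one side has no partner-sharing nodes")
    method = "exact" if max(len(pdz), len(lig)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(pdz, lig, alternative="two-sided", method=method)
    frac_pdz, _ = paralog_fraction(net, paralog_pairs, "pdz")
    frac_lig, _ = paralog_fraction(net, paralog_pairs, "ligand")
    return {
        "fraction_pdz": frac_pdz,
        "fraction_ligand": frac_lig,
        "p_value": float(res.pvalue),
        "method": method,
    }


def random_subnetwork(
    net: PdzNetwork, drop_fraction: float, unit: str, rng: np.random.Generator
) -> PdzNetwork:
    """Remove a random 20%-style fraction of nodes or edges (robustness harness)."""
    if unit not in ("nodes", "edges"):
        raise NetworkError("unit must be 'nodes' or 'edges'")
    sub = PdzNetwork(net.graph.copy())
    if unit == "nodes":
        nodes = sorted(sub.graph.nodes)
        n_drop = int(round(drop_fraction * len(nodes)))
        drop = rng.choice(len(nodes), size=n_drop, replace=False)
        sub.graph.remove_nodes_from([nodes[i] for i in drop])
    else:
        edges = sorted(sub.graph.edges)
        n_drop = int(round(drop_fraction * len(edges)))
        drop = rng.choice(len(edges), size=n_drop, replace=False)
        sub.graph.remove_edges_from([edges[i] for i in drop])
    return sub
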
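"""Layered biological hierarchy: the topology of the survival network.

A :class:`BioHierarchy` holds the four levels (gene, protein, pathway,
survival), one binary intra-level adjacency per level, and one binary
inter-level map per adjacent pair of levels.  The combination of adjacencies
and maps defines the whole network structure: message passing happens within
a level along its adjacency, and propagation to the next level is masked by
the inter-level map, so absent biological relations contribute exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import TrueHierarchy

LEVELS = ("gene", "protein", "pathway", "survival")


@dataclass
class BioHierarchy:
    """Levels, binary intra-level adjacencies A^l, and inter-level maps M^l.

    ``adjacency[level]`` is square over that level's nodes with 0/1 entries;
    ``maps[level]`` sends level-l nodes to level-(l+1) nodes and is shaped
    (n_{l+1}, n_l).  The survival level has exactly one node.
    """

    nodes: dict                      # level -> list of node ids
    adjacency: dict                  # level -> (n_l, n_l) 0/1 array
    maps: dict = field(default_factory=dict)   # level -> (n_{l+1}, n_l) 0/1 array

    def __post_init__(self):
        self.validate()

    @property
    def levels(self):
        return LEVELS

    def n(self, level: str) -> int:
        return len(self.nodes[level])

    def validate(self) -> None:
        assert set(self.nodes) == set(LEVELS), "all four levels required"
        assert self.n("survival") == 1, "survival level must have exactly one node"
        for lvl in LEVELS:
            a = self.adjacency[lvl]
            n = self.n(lvl)
            assert a.shape == (n, n), f"adjacency shape mismatch at {lvl}"
            assert set(np.unique(a)) <= {0.0, 1.0}, f"non-binary adjacency at {lvl}"
        for lvl, nxt in zip(LEVELS[:-1], LEVELS[1:]):
            m = self.maps[lvl]
            assert m.shape == (self.n(nxt), self.n(lvl)), f"map shape mismatch at {lvl}"
            assert set(np.unique(m)) <= {0.0, 1.0}, f"non-binary map at {lvl}"

    @classmethod
    def from_true_hierarchy(cls, hier: TrueHierarchy) -> "BioHierarchy":
        """Build the model topology from a generated (or file-loaded) hierarchy.

        Every pathway is connected to the single survival node.
        """
        nodes = {
            "gene": list(hier.genes),
            "protein": list(hier.proteins),
            "pathway": list(hier.pathways),
            "survival": ["survival"],
        }
        idx = {lvl: {v: i for i, v in enumerate(nodes[lvl])} for lvl in nodes}

        def adj(level, edges):
            n = len(nodes[level])
            a = np.zeros((n, n))
            for u, v in edges:
                a[idx[level][u], idx[level][v]] = 1.0
                a[idx[level][v], idx[level][u]] = 1.0
            return a

        def level_map(src, dst, pairs):
            m = np.zeros((len(nodes[dst]), len(nodes[src])))
            for child, parent in pairs:
                m[idx[dst][parent], idx[src][child]] = 1.0
            return m

        adjacency = {
            "gene": adj("gene", hier.gene_edges),
            "protein": adj("protein", hier.protein_edges),
            "pathway": adj("pathway", hier.pathway_edges),
            "survival": np.zeros((1, 1)),
        }
        maps = {
            "gene": level_map("gene", "protein", hier.gene_to_protein),
            "protein": level_map("protein", "pathway", hier.protein_to_pathway),
            "pathway": np.ones((1, len(nodes["pathway"]))),
        }
        return cls(nodes=nodes, adjacency=adjacency, maps=maps)
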
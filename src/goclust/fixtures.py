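"""Synthetic planted-structure fixtures: miniature ontologies plus enrichment
tables with known gene-sharing blocks.

A :class:`PlantedDesign` describes blocks of GO terms that share a controlled
fraction of their gene members.  Within a block every term carries the block's
core genes (``within_block_shared_fraction`` of its gene count), so every
within-block pair has overlap coefficient at least that fraction; terms in
different blocks share only the global fraction ``between_block_shared_fraction``
(zero by default, i.e. disjoint blocks).  The generator emits a matching
miniature ontology (each block a branch under a shared namespace root), the
enrichment table in the generic TSV dialect, and the true assignment per term
— everything needed to verify that clustering recovers the plant exactly.

Two-level designs (``levels=2``) plant sub-blocks inside each block.  Terms
share ``sub_shared_fraction`` of their genes within a sub-block and nothing
across sub-blocks; block-level cohesion comes from *connector* terms whose
gene sets straddle all sub-block cores and whose reference annotation size n
is drawn above the typical sub-clustering trim cutoff.  A main run keeps the
connectors and recovers whole blocks; a sub-clustering run with a tighter
``max_size`` trims the connectors away ("not passed") and recovers the
sub-blocks — the same mechanism by which lowering the term-size cutoff on
real data exposes sub-structure glued together by broad terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import EnrichedTerm, EnrichmentList, format_generic
from .ontology import OntologyGraph, OntologyTerm, write_obo


class DesignError(ValueError):
    """Infeasible planted-design parameters."""


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of one planted-block fixture (see module docstring)."""

    n_blocks: int = 2
    terms_per_block: int = 5
    genes_per_term: int = 20
    within_block_shared_fraction: float = 0.8
    between_block_shared_fraction: float = 0.0
    n_value_range: tuple = (50, 1800)
    p_value_range: tuple = (1e-12, 0.05)
    seed: int = 1
    levels: int = 1
    # two-level designs only:
    sub_blocks_per_block: int = 2
    sub_shared_fraction: float = 0.8
    n_connectors_per_block: int = 2
    connector_n_range: tuple = (2001, 3400)

    def validate(self) -> "PlantedDesign":
        g = self.genes_per_term
        if self.n_blocks < 1 or self.terms_per_block < 1 or g < 1:
            raise DesignError("counts must be positive")
        if not (0.0 < self.within_block_shared_fraction <= 1.0):
            raise DesignError("within_block_shared_fraction must be in (0, 1]")
        if not (0.0 <= self.between_block_shared_fraction < 1.0):
            raise DesignError("between_block_shared_fraction must be in [0, 1)")
        if self.levels not in (1, 2):
            raise DesignError("levels must be 1 or 2")
        n_between = round(self.between_block_shared_fraction * g)
        if self.levels == 1:
            n_core = round(self.within_block_shared_fraction * g)
        else:
            if not (0.0 < self.sub_shared_fraction <= 1.0):
                raise DesignError("sub_shared_fraction must be in (0, 1]")
            if self.sub_blocks_per_block < 2:
                raise DesignError("two-level designs need >= 2 sub-blocks per block")
            n_core = round(self.sub_shared_fraction * g)
            k = (g - n_between) // self.sub_blocks_per_block
            if k < 1 or k > n_core:
                raise DesignError(
                    "connector terms cannot straddle the sub-block cores: "
                    f"{k} genes per core needed, core holds {n_core}")
        if n_core < 1:
            raise DesignError("shared fraction too small to plant any core gene")
        if n_between + n_core > g:
            raise DesignError(
                f"shared fractions exceed the per-term gene budget: "
                f"{n_between} between + {n_core} core > {g}")
        if self.n_value_range[0] < g:
            raise DesignError("n_value_range must start at >= genes_per_term "
                              "(x <= n must hold)")
        lo, hi = self.p_value_range
        if not (0.0 < lo <= hi <= 1.0):
            raise DesignError("p_value_range must lie in (0, 1]")
        return self


@dataclass(frozen=True)
class FixtureBundle:
    """Generated fixture: OBO text, generic enrichment text, truth labels."""

    obo_text: str
    enrichment_text: str
    truth_blocks: dict       # accession -> "B<i>" (connectors included)
    truth_subblocks: dict    # accession -> "B<i>.S<j>" (two-level; no connectors)
    design: PlantedDesign


class _GeneFactory:
    def __init__(self, rng: np.random.Generator):
        self._next = 0
        # a seeded permutation of a generous id space keeps gene names
        # non-sequential without risking collisions
        self._perm = rng.permutation(100000)

    def take(self, k: int) -> frozenset:
        ids = self._perm[self._next:self._next + k]
        self._next += k
        return frozenset("G%05d" % i for i in ids)


def generate_fixture(design: PlantedDesign) -> FixtureBundle:
    """Deterministically realize ``design`` (same seed, byte-identical files)."""
    design = design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _GeneFactory(rng)
    g = design.genes_per_term

    n_between = round(design.between_block_shared_fraction * g)
    global_core = genes.take(n_between) if n_between else frozenset()

    def rand_n(rng_range) -> int:
        lo, hi = rng_range
        return int(rng.integers(lo, hi + 1))

    def rand_p() -> float:
        lo, hi = design.p_value_range
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    acc_counter = [1]

    def next_acc() -> str:
        acc = "GO:%07d" % acc_counter[0]
        acc_counter[0] += 1
        return acc

    root = next_acc()
    oterms = {root: OntologyTerm(id=root, name="biological_process",
                                 namespace="biological_process")}
    eterms: list[EnrichedTerm] = []
    truth_blocks: dict = {}
    truth_sub: dict = {}

    def add_branch(name: str, parent: str) -> str:
        acc = next_acc()
        oterms[acc] = OntologyTerm(id=acc, name=name,
                                   namespace="biological_process",
                                   parents_is_a=frozenset({parent}))
        return acc

    def add_term(name: str, parent: str, gene_set: frozenset,
                 n_range) -> EnrichedTerm:
        acc = add_branch(name, parent)
        term = EnrichedTerm(
            go_id=acc, description=name, p_value=rand_p(),
            genes=gene_set, n=max(rand_n(n_range), len(gene_set)),
            namespace="biological_process")
        eterms.append(term)
        return term

    for b in range(1, design.n_blocks + 1):
        block_label = f"B{b}"
        branch = add_branch(f"block {b} process", root)
        if design.levels == 1:
            core = genes.take(round(design.within_block_shared_fraction * g))
            for t in range(1, design.terms_per_block + 1):
                unique = genes.take(g - len(core) - len(global_core))
                term = add_term(f"block {b} term {t}", branch,
                                global_core | core | unique,
                                design.n_value_range)
                truth_blocks[term.go_id] = block_label
        else:
            n_core = round(design.sub_shared_fraction * g)
            sub_cores = []
            for s in range(1, design.sub_blocks_per_block + 1):
                sub_branch = add_branch(f"block {b} theme {s}", branch)
                core = genes.take(n_core)
                sub_cores.append(core)
                for t in range(1, design.terms_per_block + 1):
                    unique = genes.take(g - n_core - len(global_core))
                    term = add_term(f"block {b} theme {s} term {t}", sub_branch,
                                    global_core | core | unique,
                                    design.n_value_range)
                    truth_blocks[term.go_id] = block_label
                    truth_sub[term.go_id] = f"{block_label}.S{s}"
            # broad connector terms: straddle every sub-core; n above the
            # typical sub-run trim cutoff so a tighter trim removes them
            k = (g - n_between) // design.sub_blocks_per_block
            picks: set = set()
            for core in sub_cores:
                picks |= set(sorted(core)[:k])
            for c in range(1, design.n_connectors_per_block + 1):
                term = add_term(f"block {b} broad process {c}", branch,
                                global_core | frozenset(picks),
                                design.connector_n_range)
                truth_blocks[term.go_id] = block_label

    elist = EnrichmentList(terms=tuple(eterms), source_dialect="generic",
                           source_path="<fixture>")
    graph = OntologyGraph(oterms, data_version=f"fixture-seed{design.seed}")
    return FixtureBundle(
        obo_text=write_obo(graph),
        enrichment_text=format_generic(elist),
        truth_blocks=truth_blocks,
        truth_subblocks=truth_sub,
        design=design,
    )


def save_fixture(bundle: FixtureBundle, outdir) -> dict:
    """Write mini.obo, enrichment.tsv and truth.tsv under ``outdir``."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "mini.obo",
        "enrichment": outdir / "enrichment.tsv",
        "truth": outdir / "truth.tsv",
    }
    paths["obo"].write_text(bundle.obo_text, encoding="utf-8")
    paths["enrichment"].write_text(bundle.enrichment_text, encoding="utf-8")
    lines = ["GO_ID\tBlock\tSub_block"]
    for acc in sorted(bundle.truth_blocks):
        lines.append(f"{acc}\t{bundle.truth_blocks[acc]}"
                     f"\t{bundle.truth_subblocks.get(acc, '')}")
    paths["truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
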
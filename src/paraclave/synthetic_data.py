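"""Synthetic fixture generators with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and an integer seed,
and returns a ground-truth record alongside the data so that downstream
detectors can be scored for precision/recall without re-deriving truth.

The protein mutation model is substitutions-only (uniform over the 19
alternative residues, no indels), which keeps expected pairwise identity
analytically controllable.  DNA evolution is Jukes-Cantor, matching the
scale on which the alignment-free distances are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_model import AnnotationMap, OntologyDag, Protein, Proteome

AA = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one planted paralog family.

    ``target_identity`` is the expected pairwise sequence identity between
    any two family members (not member vs. ancestor).
    """

    family_size: int
    target_identity: float
    protein_length: int
    cog_category: str | None = None
    annotation_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target_identity must be in (0, 1]")
        if self.protein_length < 30:
            raise ValueError("protein_length must be >= 30")


def _mutation_rate(target_identity: float) -> float:
    """Per-site ancestor->member substitution probability q.

    Two members independently mutated at rate q match at a site with
    probability (1-q)^2 + q^2/19 (both unchanged, or both changed to the
    same of 19 alternatives); solving that quadratic for the requested
    pairwise identity gives q.
    """
    t = target_identity
    disc = 1.0 - (20.0 / 19.0) * (1.0 - t)
    if disc < 0:  # identity too low to be reachable pairwise; saturate
        return 19.0 / 20.0
    return (19.0 / 20.0) * (1.0 - np.sqrt(disc))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, 20, size=length)])


def _mutate_protein(rng: np.random.Generator, seq: str, q: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < q
    n = int(hit.sum())
    if n:
        aa = np.frombuffer(AA.encode(), dtype=np.uint8)
        # draw a uniform *different* residue at each mutated site
        cur = arr[hit]
        idx = np.searchsorted(aa, cur)
        offs = rng.integers(1, 20, size=n)
        arr[hit] = aa[(idx + offs) % 20]
    return arr.tobytes().decode()


def generate_proteome(
    family_specs: list[FamilySpec],
    n_singletons: int,
    genome_size: int,
    seed: int,
    organism_id: str = "ORG",
    species_label: str | None = None,
    strain_label: str = "",
    singleton_length: int = 150,
) -> tuple[Proteome, pd.DataFrame]:
    """Build a proteome of planted paralog families plus random singletons.

    Returns the proteome and a truth table with one row per protein
    (columns: protein_id, family, is_paralog).
    """
    rng = np.random.default_rng(seed)
    proteins: list[Protein] = []
    truth_rows: list[dict] = []
    for fi, spec in enumerate(family_specs):
        q = _mutation_rate(spec.target_identity)
        ancestor = _random_protein(rng, spec.protein_length)
        for mi in range(spec.family_size):
            pid = f"{organism_id}_F{fi:02d}_{mi:02d}"
            seq = _mutate_protein(rng, ancestor, q)
            cogs = frozenset(spec.cog_category) if spec.cog_category else frozenset()
            proteins.append(Protein(pid, seq, cogs))
            truth_rows.append(
                {"protein_id": pid, "family": fi, "is_paralog": spec.family_size > 1}
            )
    for si in range(n_singletons):
        pid = f"{organism_id}_S{si:03d}"
        proteins.append(Protein(pid, _random_protein(rng, singleton_length)))
        truth_rows.append({"protein_id": pid, "family": -1, "is_paralog": False})
    proteome = Proteome(
        organism_id=organism_id,
        species_label=species_label or organism_id,
        strain_label=strain_label,
        proteins=proteins,
        genome_size=genome_size,
    )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "family", "is_paralog"])
    return proteome, truth


def generate_go_dag(
    n_terms: int,
    n_roots: int = 1,
    mean_parents: float = 1.3,
    part_of_fraction: float = 0.2,
    seed: int = 0,
) -> OntologyDag:
    """Random acyclic ontology: parents are drawn only from earlier terms.

    Each root founds a namespace (cycled over process/function/component);
    non-root terms inherit the namespace of their first parent and any
    extra parents are drawn from the same namespace.
    """
    if not 1 <= n_roots <= n_terms:
        raise ValueError("need n_terms >= n_roots >= 1")
    if mean_parents < 1:
        raise ValueError("mean_parents must be >= 1")
    rng = np.random.default_rng(seed)
    ns_cycle = ["process", "function", "component"]
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    namespaces: dict[str, str] = {}
    names = {t: f"synthetic term {t}" for t in terms}
    edges: set[tuple[str, str, str]] = set()
    by_ns: dict[str, list[int]] = {}
    for i, term in enumerate(terms):
        if i < n_roots:
            ns = ns_cycle[i % 3]
        else:
            first = int(rng.integers(0, i))
            ns = namespaces[terms[first]]
            pool = by_ns[ns]
            n_parents = 1 + int(rng.poisson(mean_parents - 1.0))
            parents = {first}
            extra = [p for p in pool if p != first]
            if extra and n_parents > 1:
                k = min(n_parents - 1, len(extra))
                parents.update(rng.choice(extra, size=k, replace=False).tolist())
            for p in sorted(parents):
                rel = "part_of" if rng.random() < part_of_fraction else "is_a"
                edges.add((term, terms[p], rel))
        namespaces[term] = ns
        by_ns.setdefault(ns, []).append(i)
    return OntologyDag(terms, edges, namespaces, names)


def generate_annotations(
    proteomes: list[Proteome],
    paranomes: dict[str, set[str]],
    dag: OntologyDag,
    planted: dict[str, list[tuple[str, float]]],
    base_rate: float = 0.05,
    seed: int = 0,
    term_pool: list[str] | None = None,
) -> tuple[AnnotationMap, pd.DataFrame]:
    """Annotate proteins with ontology terms, planting enrichment in paranomes.

    Background proteins receive each term of ``term_pool`` (default: all
    non-root terms) independently at ``base_rate``; for each planted
    ``(term, fold)`` the organism's paranome proteins receive the term at
    ``min(1, base_rate * fold)``, or with certainty when ``base_rate`` is
    zero (so a signal-free background still carries the planted signal).
    Returns the (propagated) annotation map and a truth table of planted
    (organism, term, fold) rows.
    """
    from .go_enrichment import propagate  # local import to avoid a cycle

    for org, entries in planted.items():
        for term, fold in entries:
            if fold < 1:
                raise ValueError(f"planted fold for {org}/{term} must be >= 1")
            if term not in dag:
                raise ValueError(f"planted term {term} not in ontology")
    rng = np.random.default_rng(seed)
    pool = sorted(term_pool if term_pool is not None else (dag.terms - dag.roots))
    direct: dict[str, set[str]] = {}
    for proteome in sorted(proteomes, key=lambda p: p.organism_id):
        planted_here = dict(planted.get(proteome.organism_id, []))
        paranome = paranomes.get(proteome.organism_id, set())
        for protein in proteome.proteins:
            terms: set[str] = set()
            if base_rate > 0 and pool:
                hits = rng.random(len(pool)) < base_rate
                terms.update(t for t, h in zip(pool, hits) if h)
            if protein.id in paranome:
                for term, fold in planted_here.items():
                    p_hit = min(1.0, base_rate * fold) if base_rate > 0 else 1.0
                    if rng.random() < p_hit:
                        terms.add(term)
            direct[protein.id] = terms
    truth = pd.DataFrame(
        [
            {"organism_id": org, "term": term, "fold": fold}
            for org in sorted(planted)
            for term, fold in sorted(planted[org])
        ],
        columns=["organism_id", "term", "fold"],
    )
    return propagate(AnnotationMap(direct=direct), dag), truth


def generate_incidence(
    n_species: int,
    n_terms: int,
    planted_biclusters: list[tuple[list[int], list[int]]],
    noise_p: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[list[str], list[str]]]]:
    """Binary species x term matrix with planted all-ones blocks plus noise.

    Cells outside the planted blocks are Bernoulli(``noise_p``).  Returns
    the matrix (rows ``S###``, columns ``T###``) and the planted blocks as
    label lists.
    """
    rng = np.random.default_rng(seed)
    mat = (rng.random((n_species, n_terms)) < noise_p).astype(int)
    truth = []
    rows = [f"S{i:03d}" for i in range(n_species)]
    cols = [f"T{j:03d}" for j in range(n_terms)]
    for ridx, cidx in planted_biclusters:
        mat[np.ix_(ridx, cidx)] = 1
        truth.append(([rows[i] for i in sorted(ridx)], [cols[j] for j in sorted(cidx)]))
    return pd.DataFrame(mat, index=rows, columns=cols), truth


# ---------------------------------------------------------------------------
# DNA / tree simulation
# ---------------------------------------------------------------------------


@dataclass
class SimTree:
    """A phylogeny with branch lengths in expected substitutions per site."""

    tree: dendropy.Tree = field(repr=False)

    @classmethod
    def from_newick(cls, newick: str) -> "SimTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree=tree)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def true_distance_matrix(self) -> pd.DataFrame:
        """Pairwise leaf-to-leaf path lengths."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        d = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d[i, j] = d[j, i] = pdm.distance(taxa[a], taxa[b])
        return pd.DataFrame(d, index=labels, columns=labels)


def _jc_evolve(rng: np.random.Generator, seq: np.ndarray, t: float) -> np.ndarray:
    """Evolve a 0..3-encoded sequence for branch length t under Jukes-Cantor."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def generate_16s_set(
    tree: SimTree, seq_length: int, seed: int
) -> tuple[dict[str, str], pd.DataFrame]:
    """Evolve rDNA-like sequences along ``tree`` under Jukes-Cantor.

    The root sequence is uniform over ACGT.  Returns leaf label -> sequence
    and the true pairwise path-length distance matrix.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}
    state = {id(tree.tree.seed_node): root_seq}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            seq = state[id(node)]
        else:
            t = node.edge.length or 0.0
            seq = _jc_evolve(rng, state[id(node.parent_node)], t)
            state[id(node)] = seq
        if node.is_leaf():
            seqs[node.taxon.label] = seq
    alphabet = np.frombuffer(DNA.encode(), dtype=np.uint8)
    decoded = {
        label: alphabet[seq].tobytes().decode() for label, seq in sorted(seqs.items())
    }
    return decoded, tree.true_distance_matrix()


# ---------------------------------------------------------------------------
# bundled demo world
# ---------------------------------------------------------------------------

#: term IDs used by the demo ontology
DEMO_ROOT = "GO:0000001"
DEMO_CHAIN = ["GO:0000002", "GO:0000003", "GO:0000004", "GO:0000005"]
DEMO_PLANTED_TERMS = ("GO:0000006", "GO:0000007")
DEMO_POOL = [f"GO:{100 + i:07d}" for i in range(1, 41)]
DEMO_PLANTED_ORGS = ("ORG01", "ORG02", "ORG03", "ORG07", "ORG08", "ORG09")


def _demo_dag() -> OntologyDag:
    """Ontology for the demo world: a deep is_a chain with two sibling leaves.

    The two planted leaves sit five is_a steps below the root, deep enough
    that their graph-based similarity (0.729) clears the 0.7 convergence
    cut, while the 40 background pool terms hang directly off the root.
    """
    terms = [DEMO_ROOT, *DEMO_CHAIN, *DEMO_PLANTED_TERMS, *DEMO_POOL]
    edges: set[tuple[str, str, str]] = set()
    parent = DEMO_ROOT
    for t in DEMO_CHAIN:
        edges.add((t, parent, "is_a"))
        parent = t
    for leaf in DEMO_PLANTED_TERMS:
        edges.add((leaf, DEMO_CHAIN[-1], "is_a"))
    for t in DEMO_POOL:
        edges.add((t, DEMO_ROOT, "is_a"))
    namespaces = {t: "process" for t in terms}
    names = {t: f"demo term {t}" for t in terms}
    return OntologyDag(terms, edges, namespaces, names)


def build_demo_world(path, seed: int = 0) -> "pathlib.Path":
    """Write the bundled 12-organism synthetic world and its run config.

    Two clades of six organisms sit 0.27 substitutions/site apart (0.02
    within clades).  Three organisms in each clade carry a planted pair of
    sibling ontology terms annotated across their whole paranome, so the
    full pipeline should recover exactly one high-similarity,
    high-divergence bicluster joining those six organisms.  Background
    annotations are uniform noise, and the planted terms' ancestors are
    masked by annotating them directly on most background proteins.

    Returns the path of the written ``config.yaml``.
    """
    import json
    import pathlib

    import yaml

    from .core_model import (
        write_annotations,
        write_fasta,
        write_obo,
        write_tsv,
    )

    out = pathlib.Path(path)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    orgs = [f"ORG{i:02d}" for i in range(1, 13)]
    planted_orgs = set(DEMO_PLANTED_ORGS)
    species = {org: f"Demospecies {chr(ord('a') + i)}" for i, org in enumerate(orgs)}
    species["ORG12"] = species["ORG11"]  # two strains of one species

    # --- ontology + annotations -----------------------------------------
    dag = _demo_dag()
    write_obo(dag, out / "go.obo")

    # --- proteomes -------------------------------------------------------
    cog_cycle = ["C", "P", "N", "T", "E", "G", "K", "M"]
    meta_rows = []
    paranome_truth: dict[str, set[str]] = {}
    all_proteomes: list[Proteome] = []
    singleton_ids: list[str] = []
    for org in orgs:
        n_families = 4 if org in planted_orgs else 8
        n_singletons = 30 if org in planted_orgs else 20
        specs = [
            FamilySpec(
                family_size=3,
                target_identity=0.9,
                protein_length=120,
                cog_category=cog_cycle[fi % len(cog_cycle)],
            )
            for fi in range(n_families)
        ]
        proteome, truth = generate_proteome(
            specs,
            n_singletons=n_singletons,
            genome_size=int(rng.integers(2_000_000, 6_000_000)),
            seed=int(rng.integers(0, 2**31 - 1)),
            organism_id=org,
            species_label=species[org],
            strain_label="strain-1" if org != "ORG12" else "strain-2",
            singleton_length=120,
        )
        all_proteomes.append(proteome)
        paranome_truth[org] = set(truth[truth.is_paralog].protein_id)
        singleton_ids.extend(truth[~truth.is_paralog].protein_id)
        write_fasta(
            [(p.id, p.sequence) for p in proteome.proteins],
            out / "proteomes" / f"{org}.faa",
        )
        table_rows = []
        for p in proteome.proteins:
            if p.cog_categories:
                cog = "".join(sorted(p.cog_categories))
            elif rng.random() < 0.7:
                cog = str(rng.choice(["J", "L", "D", "F", "O", "E"]))
            else:
                cog = "-"
            table_rows.append({"protein_id": p.id, "COG": cog})
        write_tsv(pd.DataFrame(table_rows), out / "tables" / f"{org}.tsv")
        meta_rows.append(
            {
                "organism_id": org,
                "species_label": species[org],
                "strain_label": proteome.strain_label,
                "genome_size": proteome.genome_size,
            }
        )
    write_tsv(pd.DataFrame(meta_rows), out / "organisms.tsv")

    # --- annotations ------------------------------------------------------
    t1, t2 = DEMO_PLANTED_TERMS
    mask_parent = DEMO_CHAIN[-1]
    direct: dict[str, set[str]] = {}
    for proteome in all_proteomes:
        in_planted_paranome = (
            paranome_truth[proteome.organism_id]
            if proteome.organism_id in planted_orgs
            else set()
        )
        for p in proteome.proteins:
            terms: set[str] = {
                t for t in DEMO_POOL if rng.random() < 0.04
            }
            if p.id in in_planted_paranome:
                terms |= {t1, t2}
            elif rng.random() < 0.8:
                # mask the planted terms' ancestors in the background
                terms.add(mask_parent)
            direct[p.id] = terms
    write_annotations(direct, out / "annotations.tsv")

    # --- 16S-like sequences ----------------------------------------------
    clade_a = ",".join(f"ORG{i:02d}:0.01" for i in range(1, 7))
    clade_b = ",".join(f"ORG{i:02d}:0.01" for i in range(7, 13))
    tree = SimTree.from_newick(f"(({clade_a}):0.125,({clade_b}):0.125);")
    seqs, true_d = generate_16s_set(tree, 5000, seed=int(rng.integers(0, 2**31 - 1)))
    write_fasta(sorted(seqs.items()), out / "sixteen_s.fna")

    (out / "singletons.tsv").write_text("\n".join(sorted(singleton_ids)) + "\n")

    config = {
        "proteome_dir": "proteomes",
        "table_dir": "tables",
        "obo_path": "go.obo",
        "annotations_path": "annotations.tsv",
        "sixteen_s_path": "sixteen_s.fna",
        "organisms_path": "organisms.tsv",
        "singletons_path": "singletons.tsv",
        "seed": seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    truth = {
        "planted_organisms": sorted(planted_orgs),
        "planted_terms": [t1, t2],
        "paranomes": {org: sorted(ids) for org, ids in sorted(paranome_truth.items())},
        "within_clade_distance": 0.02,
        "between_clade_distance": 0.27,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out / "config.yaml"
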
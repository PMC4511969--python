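"""Synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters including the seed
(identical inputs give bit-identical outputs) and returns its output
together with a machine-readable truth record holding everything needed
to score recovery. The generators emulate the statistical structure the
analyses assume — branch-specific selection on codon alignments (with an
optional mid-branch constraint-to-neutral shift), GC-dependent coverage
with collapsed multi-copy regions, receptor families with tunable
per-species diversity, shotgun reads for the k-mer spectrum, gene-category
tables with planted enrichment, and diverged conserved-element orthologs.
They do not emulate alignment error, indel processes, read quality decay,
or assembly artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_alignment import CodonAlignment
from .codon_model import BACKGROUND, FOREGROUND, CodonModelParams, SpectralCodonMatrix, build_rate_matrix
from .entropy import AMINO_ACIDS
from .genetics import UNIVERSAL_CODE
from .phylo import PhyloTree

# Eight-species study scaffold: a ratite clade (focal nocturnal species,
# ostrich, tinamou), two night birds, and three model galliform/passerine
# genomes, with branch lengths in expected substitutions per codon typical
# of a class-wide ortholog screen.
DEMO_BIRD_NEWICK = (
    "((kiwi:0.12,(ostrich:0.10,tinamou:0.11):0.04):0.05,"
    "((chuck_wills_widow:0.09,barn_owl:0.10):0.04,"
    "(chicken:0.08,(turkey:0.07,zebra_finch:0.09):0.03):0.04):0.02);"
)


def demo_bird_tree(foreground: str = "kiwi") -> PhyloTree:
    tree = PhyloTree.from_newick(DEMO_BIRD_NEWICK)
    return tree.with_foreground_taxon(foreground) if foreground else tree


@dataclass
class SimulationConfig:
    """Seed plus free-form scenario parameters for a generator run."""

    seed: int
    params: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw_markov_states(parent_states, P, rng):
    """Child states from parent states through transition matrix P."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(parent_states))
    rows = cum[parent_states]
    return (rows < u[:, None]).sum(axis=1)


def simulate_codon_alignment(
    tree: PhyloTree,
    params: CodonModelParams,
    n_codons: int,
    seed: int,
    shift=None,
):
    """Evolve a codon alignment down the tree under the branch model.

    ``shift=(taxon, fraction)`` splits the terminal branch of ``taxon``
    into an older constrained era (the branch's class omega) followed by a
    recent neutral era (omega = 1) spanning ``fraction`` of the branch's
    *time* — the generative model behind loss-of-constraint dating. The
    two eras share a synonymous clock (equal synonymous rates per unit
    time), so a single omega refit to the whole branch estimates the
    time-weighted average omega_c * (1 - fraction) + 1 * fraction, which
    is exactly what the dating closed form inverts. The truth record
    carries every parameter plus that implied branch-average omega.
    """
    rng = _rng(seed)
    code = params.code
    pi = params.pi
    dec_bg = SpectralCodonMatrix(build_rate_matrix(params, code, BACKGROUND), pi)
    dec_fg = (
        dec_bg
        if params.omega_foreground == params.omega_background
        else SpectralCodonMatrix(build_rate_matrix(params, code, FOREGROUND), pi)
    )
    dec_neutral = SpectralCodonMatrix(
        build_rate_matrix(params.with_omega(background=1.0, foreground=1.0), code, BACKGROUND),
        pi,
    )

    shift_node = None
    if shift is not None:
        taxon, fraction = shift
        if taxon not in tree.taxa:
            raise ValueError(f"shift branch {taxon!r} is not a taxon of the tree")
        if not (0.0 <= fraction <= 1.0):
            raise ValueError("shift fraction must lie in [0, 1]")
        shift_node = tree.taxa.index(taxon)

    def syn_fraction(omega_b, omega_f, branch_class):
        p = params.with_omega(background=omega_b, foreground=omega_f)
        Q = build_rate_matrix(p, code, branch_class)
        ii, jj, _, ns = code.neighbor_table()
        flow = pi[ii] * Q[ii, jj]
        return flow[~ns].sum() / flow.sum()

    states = {tree.root: rng.choice(code.n_states, size=n_codons, p=pi)}
    for node in reversed(tree.postorder()):
        for c in tree.children[node]:
            t = tree.lengths[c]
            dec = dec_fg if tree.foreground[c] else dec_bg
            if c == shift_node:
                # common synonymous clock: both era matrices are unit-rate,
                # so the neutral era must run faster by the ratio of
                # synonymous flow fractions for its per-time synonymous
                # rate to match the constrained era's
                omega_class = (
                    params.omega_foreground if tree.foreground[c] else params.omega_background
                )
                ps_c = syn_fraction(omega_class, omega_class, BACKGROUND)
                ps_n = syn_fraction(1.0, 1.0, BACKGROUND)
                clock = ps_c / ps_n
                P = dec.transition_matrix(t * (1.0 - fraction)) @ dec_neutral.transition_matrix(
                    clock * t * fraction
                )
            else:
                P = dec.transition_matrix(t)
            states[c] = (
                _draw_markov_states(states[node], P, rng)
                if n_codons
                else np.empty(0, dtype=int)
            )

    codons = code.sense_codons
    seqs = [
        "".join(codons[s] for s in states[i]) for i in range(tree.n_leaves)
    ]
    aln = CodonAlignment(list(tree.taxa), seqs, code)
    truth = {
        "seed": int(seed),
        "n_codons": int(n_codons),
        "kappa": params.kappa,
        "omega_background": params.omega_background,
        "omega_foreground": params.omega_foreground,
        "tree": tree.to_newick(),
    }
    if shift is not None:
        omega_class = (
            params.omega_foreground if tree.foreground[shift_node] else params.omega_background
        )
        truth.update(
            shift_taxon=shift[0],
            shift_fraction=float(shift[1]),
            expected_branch_average_omega=omega_class * (1 - shift[1]) + 1.0 * shift[1],
        )
    return aln, truth


def flat_gc_bias(gc):
    return np.ones_like(np.asarray(gc, dtype=float))


def gaussian_gc_bias(gc, optimum: float = 0.45, width: float = 0.25):
    """Unimodal amplification bias: depth falls off at extreme GC."""
    gc = np.asarray(gc, dtype=float)
    return np.exp(-0.5 * ((gc - optimum) / width) ** 2)


def simulate_coverage_track(
    genome_length: int,
    mean_depth: float = 35.0,
    gc_profile=None,
    gc_bias=None,
    copy_map: dict = None,
    noise: str = "poisson",
    window: int = 200,
    seed: int = 0,
):
    """Per-window read-depth track with GC bias and collapsed duplications.

    Window depth ~ Poisson(mean_depth * bias(gc) * copy_number) (or the
    deterministic mean with ``noise='none'``). ``copy_map`` maps region id
    -> (start_bp, end_bp, copies); windows inside a region carry its copy
    number, emulating a multi-copy family collapsed onto one assembly
    locus. Returns (track dict of arrays, truth record).
    """
    rng = _rng(seed)
    n_windows = genome_length // window
    if n_windows == 0:
        raise ValueError("genome shorter than one window")
    if gc_profile is None:
        gc = np.clip(rng.normal(0.42, 0.08, size=n_windows), 0.05, 0.95)
    else:
        gc = np.asarray(gc_profile, dtype=float)
        if len(gc) != n_windows:
            raise ValueError("gc_profile length must equal the window count")
    bias = (gc_bias or flat_gc_bias)(gc)
    copies = np.ones(n_windows)
    copy_map = copy_map or {}
    for rid, (start, end, c) in copy_map.items():
        if c < 1 or int(c) != c:
            raise ValueError(f"copy number for {rid!r} must be an integer >= 1")
        copies[start // window : max(end // window, start // window + 1)] = c
    lam = mean_depth * bias * copies
    if noise == "poisson":
        depth = rng.poisson(lam).astype(float)
    elif noise == "none":
        depth = lam.copy()
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    track = {
        "window": window,
        "start": np.arange(n_windows) * window,
        "gc": gc,
        "depth": depth,
    }
    truth = {
        "seed": int(seed),
        "genome_length": int(genome_length),
        "mean_depth": float(mean_depth),
        "noise": noise,
        "copy_map": {k: [int(v[0]), int(v[1]), int(v[2])] for k, v in copy_map.items()},
    }
    return track, truth


def write_depth_tsv(track, path, chrom: str = "chr1"):
    """Expand a window track to per-position samtools-depth TSV."""
    window = track["window"]
    with open(path, "w") as fh:
        for start, depth in zip(track["start"], track["depth"]):
            for p in range(start + 1, start + window + 1):
                fh.write(f"{chrom}\t{p}\t{depth:g}\n")


def simulate_or_family(
    n_species: int = None,
    genes_per_species: int = 12,
    consensus_length: int = 100,
    per_species_divergence=None,
    seed: int = 0,
):
    """Per-species receptor-family protein alignments from one consensus.

    Each species' family members are copies of a shared consensus protein
    with independent per-position substitutions at that species' rate, so
    higher rates give higher expected column entropy. Returns
    ({species: [sequences]}, truth).
    """
    if per_species_divergence is None:
        names = [f"species_{i}" for i in range(n_species or 2)]
        per_species_divergence = {nm: 0.05 for nm in names}
    rng = _rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(len(aas), size=consensus_length)
    families = {}
    for species in sorted(per_species_divergence):
        rate = per_species_divergence[species]
        if rate < 0:
            raise ValueError("divergence rates must be nonnegative")
        seqs = []
        for _ in range(genes_per_species):
            gene = consensus.copy()
            hits = rng.random(consensus_length) < rate
            if hits.any():
                # substitute with a uniformly chosen different residue
                shift = rng.integers(1, len(aas), size=int(hits.sum()))
                gene[hits] = (gene[hits] + shift) % len(aas)
            seqs.append("".join(aas[gene]))
        families[species] = seqs
    truth = {
        "seed": int(seed),
        "consensus": "".join(aas[consensus]),
        "genes_per_species": int(genes_per_species),
        "per_species_divergence": dict(per_species_divergence),
    }
    return families, truth


def random_genome(length: int, seed: int = 0, gc: float = 0.42) -> str:
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def simulate_reads(
    genome_length: int,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Uniform shotgun reads with substitution errors from a random genome.

    Returns (reads, truth); the truth record includes the genome so k-mer
    analyses can be scored against the real size.
    """
    if read_length > genome_length:
        raise ValueError("read length exceeds genome length")
    rng = _rng(seed)
    genome = random_genome(genome_length, seed=rng.integers(2**31))
    n_reads = int(round(coverage * genome_length / read_length))
    reads = []
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for _ in range(n_reads):
        start = int(rng.integers(0, genome_length - read_length + 1))
        read = genome[start : start + read_length]
        if error_rate > 0:
            arr = np.array([base_idx[b] for b in read])
            hits = rng.random(read_length) < error_rate
            if hits.any():
                arr[hits] = (arr[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
                read = "".join(bases[arr])
        reads.append(read)
    truth = {
        "seed": int(seed),
        "genome_length": int(genome_length),
        "coverage": float(coverage),
        "read_length": int(read_length),
        "error_rate": float(error_rate),
        "n_reads": n_reads,
        "genome": genome,
    }
    return reads, truth


def simulate_category_data(
    n_genes: int = 1000,
    n_categories: int = 50,
    sig_fraction: float = 0.05,
    planted=None,
    categories_per_gene: int = 1,
    seed: int = 0,
):
    """Gene-category annotation with optionally planted enrichment.

    Genes are assigned to ``categories_per_gene`` random categories;
    significance flags are Bernoulli(sig_fraction) except in the planted
    category, where the odds are multiplied by the planted odds ratio.
    ``planted=(category_index, odds)``. Returns (annotation dict, list of
    significant genes, truth).
    """
    rng = _rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cats = [f"CAT:{j:04d}" for j in range(n_categories)]
    membership = {c: set() for c in cats}
    gene_cats = {}
    for g in genes:
        chosen = rng.choice(n_categories, size=categories_per_gene, replace=False)
        gene_cats[g] = [cats[j] for j in chosen]
        for j in chosen:
            membership[cats[j]].add(g)
    planted_cat = None
    if planted is not None:
        idx, odds = planted
        planted_cat = cats[idx]
        base_odds = sig_fraction / (1 - sig_fraction)
        p_planted = (odds * base_odds) / (1 + odds * base_odds)
    significant = []
    for g in genes:
        p = p_planted if planted_cat and planted_cat in gene_cats[g] else sig_fraction
        if rng.random() < p:
            significant.append(g)
    membership = {c: m for c, m in membership.items() if m}
    truth = {
        "seed": int(seed),
        "n_genes": n_genes,
        "n_categories": n_categories,
        "sig_fraction": sig_fraction,
        "planted_category": planted_cat,
        "planted_odds": None if planted is None else float(planted[1]),
    }
    return {"categories": membership, "universe": set(genes)}, significant, truth


def simulate_ucne_orthologs(catalog, divergence_map: dict, seed: int = 0):
    """Mutated orthologs of conserved elements at planted divergence rates.

    ``catalog`` is a list of UCNERecord-like objects (element_id,
    sequence); each ortholog carries independent substitutions at the
    element's mapped rate. Returns ({element_id: sequence}, truth).
    """
    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    out = {}
    for rec in catalog:
        rate = divergence_map.get(rec.element_id, 0.0)
        if rate > 1:
            raise ValueError(f"divergence for {rec.element_id!r} exceeds 1")
        arr = np.array([base_idx[b] for b in rec.sequence])
        hits = rng.random(len(arr)) < rate
        if hits.any():
            arr[hits] = (arr[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
        out[rec.element_id] = "".join(bases[arr])
    truth = {"seed": int(seed), "divergence_map": dict(divergence_map)}
    return out, truth
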
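"""Seeded generators with known truth for every pipeline stage.

The study this pipeline emulates compared coding-sequence evolution and
heterozygosity between a small-ranged partridge and its widespread
sister junglefowl across five galliform genomes; the raw sequencing data
behind it are not redistributable.  These generators stand in for them:
codon alignments evolved on the five-taxon species tree under explicit
kappa/omega regimes (including branch-site mixtures), orthogroup sets
with planted paralogous/contaminant sequences of inflated dS, diploid
variant sites with a known heterozygosity and base-error rate, and
gene-to-category annotation maps with planted enrichment.  Every
generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .codon_engine import (
    CodonModelParams,
    _EigenQ,
    build_rate_matrix,
    substitution_fluxes,
    unscaled_flux_coeffs,
)
from .genetics import N_SENSE, STANDARD_CODE
from .genome_stats import SiteCall
from .ortholog_qc import Orthogroup
from .trees import PhyloTree

__all__ = [
    "SimTruth",
    "default_species_tree",
    "SPECIES",
    "simulate_codon_alignment",
    "plant_gaps",
    "simulate_orthogroup_set",
    "simulate_variant_sites",
    "simulate_annotation_set",
]

SPECIES = ("Colinus", "Coturnix", "Meleagris", "Bambusicola", "Gallus")

# Species topology of the five galliform genomes; branch lengths are
# expected substitutions per codon, chosen to resemble the divergence
# scale of the study system (terminal partridge/junglefowl branches a few
# percent, the quail and bobwhite progressively deeper).
_DEFAULT_TREE = (
    "((Colinus:0.25,(Coturnix:0.15,(Meleagris:0.12,"
    "(Bambusicola:0.06,Gallus:0.06):0.04):0.04):0.05));"
)


def default_species_tree() -> PhyloTree:
    return PhyloTree.from_newick(_DEFAULT_TREE)


@dataclass
class SimTruth:
    """What a generator actually did: scenario, true parameters, seed."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sample_transitions(P: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    """Draw child states from the rows of P indexed by parent states."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(states.size)
    return (u[:, None] > cum[states]).sum(axis=1).astype(np.int16)


def simulate_codon_alignment(
    tree: PhyloTree,
    params: CodonModelParams,
    n_codons: int,
    seed: int,
    foreground: str | None = None,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve an ungapped codon alignment forward along a tree.

    Root codons are drawn from ``params.pi``; each branch multiplies in a
    transition matrix from the scaled rate matrix.  When ``params``
    carries a site mixture, site classes are assigned once at the root
    and kept across the whole tree (model A semantics), with the
    foreground branch using the class's foreground omega.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed)
    pi = params.pi
    mix = params.site_mixture
    fg = tree.resolve_branch(foreground) if foreground is not None else None
    if mix is not None and fg is None:
        raise ValueError("a site mixture requires a foreground branch")

    # per-site (background omega, foreground omega)
    if mix is None:
        classes = None
        site_class = np.zeros(n_codons, dtype=int)
    else:
        probs = [mix.p0, mix.p1, mix.p2a, mix.p2b]
        classes = [
            (mix.omega0, mix.omega0),
            (1.0, 1.0),
            (mix.omega0, mix.omega2),
            (1.0, mix.omega2),
        ]
        site_class = rng.choice(4, size=n_codons, p=np.array(probs) / np.sum(probs))

    index = tree.postorder_index()
    children = index.children()
    states = np.empty((index.n_nodes, n_codons), dtype=np.int16)
    states[index.root] = rng.choice(N_SENSE, size=n_codons, p=pi)

    eig_cache: dict[float, _EigenQ] = {}

    def eig_for(omega: float) -> _EigenQ:
        if omega not in eig_cache:
            eig_cache[omega] = _EigenQ(build_rate_matrix(params.kappa, omega, pi), pi)
        return eig_cache[omega]

    # preorder = reversed postorder
    rs, rn = unscaled_flux_coeffs(params.kappa, pi)
    for k in reversed(range(index.n_nodes)):
        for c in children[k]:
            bid = index.branch_ids[c]
            t = index.lengths[c]
            is_fg = bid == fg
            if mix is None:
                omega_sites = np.full(n_codons, params.omega_for_branch(bid, is_fg))
                rho = None
            else:
                omega_sites = np.array(
                    [classes[ci][1 if is_fg else 0] for ci in site_class]
                )
                # branch lengths are substitutions per codon averaged over
                # classes; keep relative class rates (same convention as the
                # likelihood engine)
                w_branch = [w_fg if is_fg else w_bg for (w_bg, w_fg) in classes]
                rho = float(
                    sum(p * (rs + w * rn) for p, w in zip(probs, w_branch))
                    / sum(probs)
                )
            child_states = np.empty(n_codons, dtype=np.int16)
            for omega in np.unique(omega_sites):
                mask = omega_sites == omega
                t_eff = t if rho is None else t * (rs + float(omega) * rn) / rho
                P = eig_for(float(omega)).prob(t_eff)
                child_states[mask] = _sample_transitions(P, states[k][mask], rng)
            states[c] = child_states

    codons = STANDARD_CODE.sense_codons
    taxa, rows = [], []
    for name, k in sorted(index.leaf_index.items()):
        taxa.append(name)
        rows.append("".join(codons[s] for s in states[k]))
    truth = SimTruth(
        scenario="codon_alignment",
        seed=seed,
        params={
            "kappa": params.kappa,
            "omega_map": dict(params.omega_map),
            "site_mixture": None if mix is None else vars(mix).copy(),
            "foreground": fg,
            "n_codons": n_codons,
            "site_class": site_class.tolist() if mix is not None else None,
        },
    )
    return CodonAlignment(taxa, rows), truth


# --------------------------------------------------------------------------
# orthogroup sets with planted contaminants
# --------------------------------------------------------------------------


def _ds_to_branch_length(ds: float, kappa: float, omega: float, pi) -> float:
    """Invert the dS definition: branch length t giving the requested dS."""
    rho_s1, rho_n1 = substitution_fluxes(kappa, 1.0, pi)
    f_s = rho_s1 / (rho_s1 + rho_n1)
    rho_s, _ = substitution_fluxes(kappa, omega, pi)
    return ds * 3.0 * f_s / rho_s


def simulate_orthogroup_set(
    n_genes: int,
    species: tuple[str, ...] = SPECIES,
    contamination_rate: float = 0.0,
    ds_shift: float = 0.8,
    seed: int = 0,
    n_codons: int | None = None,
    kappa: float = 2.0,
    omega: float = 0.2,
    ds_scale: float = 1.0,
) -> tuple[list[Orthogroup], dict[str, PhyloTree], SimTruth]:
    """Simulate single-copy orthogroups with optional planted contaminants.

    Each gene gets the species topology with per-branch dS drawn around
    the species-tree scale (gamma-distributed rate jitter); with
    probability ``contamination_rate`` one random terminal branch has its
    dS inflated by ``ds_shift``, emulating a paralog or contaminant whose
    nearest-neighbour dS is too large.  When ``n_codons`` is given, codon
    alignments are evolved on the dS-scaled gene trees and packaged as
    orthogroups (protein alignment plus CDS); otherwise sequence fields
    are left empty and only the dS gene trees are produced.
    """
    if not (0.0 <= contamination_rate <= 1.0):
        raise ValueError("contamination_rate must lie in [0, 1]")
    rng = _rng(seed)
    base = default_species_tree()
    gene_trees: dict[str, PhyloTree] = {}
    groups: list[Orthogroup] = []
    contaminated: dict[str, str | None] = {}
    uniform_pi = np.full(N_SENSE, 1.0 / N_SENSE)

    for g in range(n_genes):
        gene_id = f"og{g:04d}"
        tree = base.copy()
        lengths = tree.branch_lengths
        # per-branch dS: species-tree length * 0.5 (rough dS fraction) * gamma jitter
        ds = {
            bid: ds_scale * 0.5 * L * rng.gamma(5.0, 1.0 / 5.0) + 1e-4
            for bid, L in lengths.items()
        }
        victim = None
        if rng.random() < contamination_rate:
            victim = str(rng.choice(list(species)))
            ds[victim] = ds[victim] + ds_shift
        contaminated[gene_id] = victim
        dtree = tree.with_branch_lengths(ds)
        gene_trees[gene_id] = dtree

        members = {sp: [f"{sp}|{gene_id}"] for sp in species}
        group = Orthogroup(group_id=gene_id, members=members)
        if n_codons is not None:
            t_lengths = {
                bid: _ds_to_branch_length(d, kappa, omega, uniform_pi)
                for bid, d in ds.items()
            }
            sim_tree = tree.with_branch_lengths(t_lengths)
            params = CodonModelParams(
                kappa=kappa, omega_map={"ALL": omega}, pi=uniform_pi
            )
            aln, _ = simulate_codon_alignment(
                sim_tree, params, n_codons, seed=int(rng.integers(2**31 - 1))
            )
            from Bio.Seq import Seq

            for sp in species:
                seq_id = f"{sp}|{gene_id}"
                cds = aln.ungapped(sp)
                group.cds[seq_id] = cds
                group.protein_alignment[seq_id] = str(Seq(cds).translate())
        groups.append(group)

    truth = SimTruth(
        scenario="orthogroup_set",
        seed=seed,
        params={
            "n_genes": n_genes,
            "contamination_rate": contamination_rate,
            "ds_shift": ds_shift,
            "contaminated": contaminated,
            "kappa": kappa,
            "omega": omega,
        },
    )
    return groups, gene_trees, truth


def plant_gaps(
    alignment: CodonAlignment,
    seed: int,
    n_blocks: int = 2,
    max_block_codons: int = 3,
    skip_first: int = 1,
) -> CodonAlignment:
    """Replace random codon blocks with gaps, emulating lineage deletions.

    The input (typically an ungapped simulated alignment) is the true
    homology; the returned alignment is "correctly aligned" but gapped,
    which gives gap-shift perturbation something to misplace.  Blocks
    never touch the first ``skip_first`` codons so rows stay anchored.
    """
    rng = _rng(seed)
    n_sites = alignment.site_count
    rows = []
    for row in alignment.rows:
        units = [row[3 * s : 3 * s + 3] for s in range(n_sites)]
        for _ in range(n_blocks):
            width = int(rng.integers(1, max_block_codons + 1))
            if n_sites - skip_first - width <= 0:
                continue
            start = int(rng.integers(skip_first, n_sites - width))
            for s in range(start, start + width):
                units[s] = "---"
        rows.append("".join(units))
    return CodonAlignment(list(alignment.taxa), rows)


# --------------------------------------------------------------------------
# diploid variant sites
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_variant_sites(
    chrom_lengths: dict[str, int],
    het_rate: float = 0.0038,
    depth_mean: float = 25.0,
    error_rate: float = 0.0,
    seed: int = 0,
    error_maf: float = 0.15,
) -> tuple[list[SiteCall], dict, SimTruth]:
    """Simulate diploid site calls with known truth.

    True heterozygous positions occur at ``het_rate`` per base (the
    default mirrors the observed genome-wide scale of ~3.8 het/kb);
    read depth is Poisson around ``depth_mean`` (the assembly's ~25x)
    and allele depths at true hets are Binomial(depth, 1/2).  Erroneous
    heterozygous calls are planted at homozygous positions at rate
    ``error_rate`` with minor-allele fraction ``error_maf``.  Returns the
    variant site calls, a truth dict with per-chromosome het position
    sets, per-position callable masks (depth >= 20) and callable lengths,
    and the SimTruth record.
    """
    if not (0.0 <= het_rate <= 1.0):
        raise ValueError("het_rate must lie in [0, 1]")
    rng = _rng(seed)
    sites: list[SiteCall] = []
    het_positions: dict[str, np.ndarray] = {}
    error_positions: dict[str, np.ndarray] = {}
    callable_lengths: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        n_het = rng.binomial(length, het_rate)
        pos_het = np.sort(rng.choice(length, size=n_het, replace=False)) + 1
        n_err = rng.binomial(length - n_het, error_rate)
        taken = set(pos_het.tolist())
        pool = rng.integers(1, length + 1, size=max(4 * n_err, 16))
        pos_err = []
        for p in pool:
            if int(p) not in taken:
                taken.add(int(p))
                pos_err.append(int(p))
            if len(pos_err) == n_err:
                break
        pos_err = np.array(sorted(pos_err), dtype=int)
        het_positions[chrom] = pos_het
        error_positions[chrom] = pos_err

        # callable length: depth >= 20 across the chromosome, simulated in bulk
        depths_all = rng.poisson(depth_mean, size=length)
        callable_lengths[chrom] = int((depths_all >= 20).sum())
        callable_mask = depths_all >= 20

        for pos, is_err in [(p, False) for p in pos_het] + [(p, True) for p in pos_err]:
            depth = int(depths_all[pos - 1])
            if depth == 0:
                continue
            ref, alt = rng.choice(4, size=2, replace=False)
            maf = error_maf if is_err else 0.5
            minor = rng.binomial(depth, maf)
            if is_err:
                minor = max(1, minor)  # an emitted miscall always shows the minor allele
            elif minor == 0 or minor == depth:
                minor = max(1, min(depth - 1, minor))  # observed het shows both alleles
            sites.append(
                SiteCall(
                    chrom=chrom,
                    pos=int(pos),
                    alleles=[
                        (str(_BASES[ref]), depth - minor),
                        (str(_BASES[alt]), minor),
                    ],
                    total_depth=depth,
                    base_quality=int(rng.integers(25, 40)),
                )
            )
        het_positions[chrom] = pos_het[callable_mask[pos_het - 1]]
    truth_payload = {
        "het_positions": {c: set(map(int, p)) for c, p in het_positions.items()},
        "error_positions": {c: set(map(int, p)) for c, p in error_positions.items()},
        "callable_lengths": callable_lengths,
    }
    truth = SimTruth(
        scenario="variant_sites",
        seed=seed,
        params={
            "het_rate": het_rate,
            "depth_mean": depth_mean,
            "error_rate": error_rate,
            "chrom_lengths": dict(chrom_lengths),
        },
    )
    return sites, truth_payload, truth


# --------------------------------------------------------------------------
# annotation maps with planted enrichment
# --------------------------------------------------------------------------


def simulate_annotation_set(
    n_genes: int,
    n_categories: int,
    planted_category: str | None = None,
    odds: float = 1.0,
    seed: int = 0,
    base_sig_rate: float = 0.2,
    annotation_prob: float = 0.15,
):
    """Gene-to-category map plus significance labels with planted enrichment.

    Every gene is annotated to each category independently with
    probability ``annotation_prob``.  Significance labels are drawn from
    a logistic model whose log-odds get a ``log(odds)`` boost for genes
    annotated to ``planted_category``; ``odds = 1`` means no enrichment.
    Returns ``(annotations, names, significant, truth)``.
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    rng = _rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    categories = [f"CAT:{j:04d}" for j in range(n_categories)]
    if planted_category is not None and planted_category not in categories:
        categories[0] = planted_category
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        mask = rng.random(n_categories) < annotation_prob
        annotations[g] = {c for c, m in zip(categories, mask) if m}
    base_logit = np.log(base_sig_rate / (1.0 - base_sig_rate))
    significant: dict[str, bool] = {}
    for g in genes:
        lo = base_logit
        if planted_category is not None and planted_category in annotations[g]:
            lo += np.log(odds)
        p = 1.0 / (1.0 + np.exp(-lo))
        significant[g] = bool(rng.random() < p)
    names = {c: f"category {c.split(':')[-1]}" for c in categories}
    truth = SimTruth(
        scenario="annotation_set",
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_categories": n_categories,
            "planted_category": planted_category,
            "odds": odds,
            "base_sig_rate": base_sig_rate,
        },
    )
    return annotations, names, significant, truth
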
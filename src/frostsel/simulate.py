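"""Synthetic study-like datasets: orthologous codon alignments evolved along
the grass species tree under the branch-site codon process.

Each simulated gene draws a site class per codon (i.i.d.), samples a root
sequence from the stationary codon distribution, and evolves it branch by
branch with an exact continuous-time Markov jump process over the 61 sense
codons (stop codons have zero rate and are never generated; no indels are
simulated, so alignments are exact).  A configurable minority of genes is
labelled "LTI" (low-temperature-induced) and carries positive selection
(omega2 > 1) on a designated foreground branch; background genes evolve with
omega2 = 1.  Per-species taxon dropout and occasional long-branch
contaminants (a paralog-like sequence re-evolved on a stretched terminal
branch) emulate the failure modes the downstream QC must catch.

Branch lengths are expected substitutions per codon under the background
site-class mixture.  Defaults emulate the magnitudes of the real study
system: ~9% LTI genes, 400 codons per gene, species-to-outgroup synonymous
distances around 0.6 and aggregate dN/dS near 0.12, taxon presence
reflecting the relative coverage of the source transcriptome collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codonmodel import BranchSiteParams, gy94_raw_Q
from .genetic_code import (
    CODON_INDEX,
    CODON_NUC,
    IS_SYNONYMOUS,
    N_CODONS,
    SINGLE_STEP,
)

from .topology import ANCHOR_SPECIES, BRANCH_CLADES, SpeciesTopology

#: nonsynonymous single-step codon change mask
SINGLE_STEP_NONSYN = SINGLE_STEP & ~IS_SYNONYMOUS

#: expected substitutions per codon per branch (background process)
DEFAULT_BRANCH_LENGTHS: dict[str, float] = {
    "sorghum": 0.10, "maize": 0.12, "rice": 0.24, "brachypodium": 0.19,
    "wheat": 0.10, "barley": 0.10, "lolium": 0.10, "festuca": 0.10,
    "pacmad": 0.18, "bep": 0.08, "BP_ancestral": 0.08, "CP_stem": 0.06,
    "hordeeae": 0.06, "poeae": 0.06,
}

#: per-species probability that a gene lacks that species, mirroring the
#: relative coverage of the source sequence collections (rice and the
#: B. distachyon anchor are complete genomes and never drop out)
DEFAULT_DROPOUT: dict[str, float] = {
    "sorghum": 0.03, "maize": 0.06, "rice": 0.0, "brachypodium": 0.0,
    "wheat": 0.26, "barley": 0.13, "lolium": 0.07, "festuca": 0.59,
}

#: position-specific base frequencies (A, C, G, T) used to build the
#: stationary F3x4-style codon distribution; mildly GC-rich third positions
#: as is typical of grass coding sequence
DEFAULT_POSITION_BASE_FREQS = (
    (0.27, 0.22, 0.31, 0.20),
    (0.29, 0.23, 0.19, 0.29),
    (0.21, 0.29, 0.27, 0.23),
)


@dataclass(frozen=True)
class SiteClassConfig:
    """Site-class mixture for one gene class; background genes must have
    omega2 = 1 (no positive selection anywhere)."""

    p0: float = 0.88
    p1: float = 0.07
    omega0: float = 0.04
    omega2: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    lti_fraction: float = 0.09
    n_codons: int | tuple[int, int] = 400
    branch_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS)
    )
    kappa: float = 2.5
    background_classes: SiteClassConfig = SiteClassConfig()
    lti_classes: SiteClassConfig = SiteClassConfig(
        p0=0.787, p1=0.063, omega0=0.04, omega2=8.0
    )
    foreground_branch: str = "BP_ancestral"
    dropout_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DROPOUT)
    )
    contaminant_rate: float = 0.0
    contaminant_stretch: float = 3.5
    position_base_freqs: tuple = DEFAULT_POSITION_BASE_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name, p in [("lti_fraction", self.lti_fraction),
                        ("contaminant_rate", self.contaminant_rate),
                        *self.dropout_probs.items()]:
            if not 0 <= p <= 1:
                raise ValueError(f"probability {name} outside [0, 1]")
        for br, t in self.branch_lengths.items():
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"branch length for {br} must be finite >= 0")
        if self.background_classes.omega2 != 1.0:
            raise ValueError("background genes must have omega2 = 1")

    def codon_pi(self) -> np.ndarray:
        pos = np.asarray(self.position_base_freqs, dtype=float)
        pi = (pos[0, CODON_NUC[:, 0]] * pos[1, CODON_NUC[:, 1]]
              * pos[2, CODON_NUC[:, 2]])
        return pi / pi.sum()

    def params_for(self, gene_class: str) -> BranchSiteParams:
        cls = self.lti_classes if gene_class == "lti" else self.background_classes
        return BranchSiteParams(
            p0=cls.p0, p1=cls.p1, omega0=cls.omega0,
            omega2=max(cls.omega2, 1.0), kappa=self.kappa, pi=self.codon_pi(),
        )


class _JumpProcess:
    """Exit rates and cumulative jump distributions for one rate matrix."""

    def __init__(self, Q: np.ndarray):
        self.exit = -np.diag(Q).copy()
        jump = Q.copy()
        np.fill_diagonal(jump, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = jump / self.exit[:, None]
        jump[self.exit <= 0] = 0.0
        self.cum_jump = np.cumsum(jump, axis=1)

    def evolve(
        self, states: np.ndarray, t: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evolve states for time t; returns (new_states, n_syn, n_nonsyn)
        with per-site substitution counts."""
        states = states.copy()
        n_syn = np.zeros(states.size, dtype=np.int64)
        n_nonsyn = np.zeros(states.size, dtype=np.int64)
        remaining = np.full(states.size, float(t))
        active = np.nonzero(self.exit[states] > 0)[0]
        while active.size:
            rates = self.exit[states[active]]
            dt = rng.exponential(1.0 / rates)
            jumps = dt < remaining[active]
            idx = active[jumps]
            remaining[idx] -= dt[jumps]
            if idx.size:
                u = rng.random(idx.size)
                new = (u[:, None] < self.cum_jump[states[idx]]).argmax(axis=1)
                syn = IS_SYNONYMOUS[states[idx], new]
                np.add.at(n_syn, idx, syn)
                np.add.at(n_nonsyn, idx, ~syn)
                states[idx] = new
            active = idx[self.exit[states[idx]] > 0]
        return states, n_syn, n_nonsyn


def _tree_depth(
    topology: SpeciesTopology, branch_lengths: dict[str, float]
) -> float:
    """Maximum root-to-tip path length (substitutions/codon)."""
    tree = topology.tree()
    best = 0.0
    for leaf in tree.leaf_node_iter():
        total, node = 0.0, leaf
        while node.parent_node is not None:
            total += branch_lengths[_branch_name(node)]
            node = node.parent_node
        best = max(best, total)
    return best


def _branch_name(child_node) -> str:
    leaves = frozenset(l.taxon.label for l in child_node.leaf_iter())
    for name, clade in BRANCH_CLADES.items():
        if clade == leaves:
            return name
    raise KeyError(f"unnamed branch subtending {sorted(leaves)}")


def simulate_gene(
    topology: SpeciesTopology,
    cfg: SimulationConfig,
    gene_class: str,
    rng: np.random.Generator | int,
    contaminant_taxon: str | None = None,
) -> tuple[CodonAlignment, dict]:
    """Simulate one gene: codon alignment over all 8 taxa plus a truth row.

    ``gene_class`` is ``"lti"`` (positive selection with the configured
    omega2 on the foreground branch) or ``"background"`` (omega2 = 1).
    The truth row records site classes, realized synonymous/nonsynonymous
    substitution counts on the foreground branch and summed over background
    branches, and the contaminant taxon if one was planted.
    """
    if gene_class not in ("lti", "background"):
        raise ValueError(f"unknown gene class {gene_class!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = cfg.n_codons
    n_codons = int(n) if np.isscalar(n) else int(rng.integers(n[0], n[1] + 1))
    if n_codons < 1:
        raise ValueError("zero-length alignment requested")

    params = cfg.params_for(gene_class)
    pi = params.pi
    weights = params.class_proportions()
    omegas_bg, omegas_fg = params.class_omegas()
    scale = params.normalizer()

    processes: dict[float, _JumpProcess] = {}
    for om in set(np.concatenate([omegas_bg, omegas_fg])):
        processes[float(om)] = _JumpProcess(
            gy94_raw_Q(params.kappa, float(om), pi) / scale
        )

    site_class = rng.choice(4, size=n_codons, p=weights)
    root_seq = rng.choice(N_CODONS, size=n_codons, p=pi)

    tree = topology.tree()
    node_states = {id(tree.seed_node): root_seq}
    fg_counts = np.zeros(2, dtype=np.int64)   # syn, nonsyn
    bg_counts = np.zeros(2, dtype=np.int64)
    tip_seqs: dict[str, np.ndarray] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = _branch_name(node)
        t_len = cfg.branch_lengths[name]
        is_fg = name == cfg.foreground_branch
        parent = node_states[id(node.parent_node)]
        child = parent.copy()
        for k in range(4):
            mask = site_class == k
            if not mask.any():
                continue
            om = float(omegas_fg[k] if is_fg else omegas_bg[k])
            new, nsyn, nnon = processes[om].evolve(parent[mask], t_len, rng)
            child[mask] = new
            tgt = fg_counts if is_fg else bg_counts
            tgt += (int(nsyn.sum()), int(nnon.sum()))
        node_states[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label
            seq = child
            if label == contaminant_taxon:
                # paralog-like contaminant: re-evolve this tip from its
                # ancestral state on a branch stretched to a multiple of the
                # tree depth, guaranteeing a long external branch downstream
                depth = _tree_depth(topology, cfg.branch_lengths)
                proc = processes[1.0]
                seq, _, _ = proc.evolve(
                    parent, cfg.contaminant_stretch * depth, rng
                )
            tip_seqs[label] = seq

    matrix = np.stack([tip_seqs[t] for t in topology.taxa])
    # every CDS starts with a fixed ATG: real orthologs share the start
    # codon, and the downstream hygiene filter requires it
    matrix[:, 0] = CODON_INDEX["ATG"]
    alignment = CodonAlignment(list(topology.taxa), matrix)
    selected = np.nonzero((site_class == 2) | (site_class == 3))[0] + 1
    truth = {
        "is_lti": gene_class == "lti",
        "foreground_omega2": params.omega2,
        "n_codons": n_codons,
        "fg_syn": int(fg_counts[0]),
        "fg_nonsyn": int(fg_counts[1]),
        "bg_syn": int(bg_counts[0]),
        "bg_nonsyn": int(bg_counts[1]),
        "selected_sites": ";".join(map(str, selected)),
        "contaminant_taxon": contaminant_taxon or "",
    }
    return alignment, truth


@dataclass
class Dataset:
    """In-memory synthetic dataset: per-gene alignments (after dropout and
    contamination), the gene-level LTI label table, and the truth table."""

    genes: dict[str, CodonAlignment]
    labels: pd.DataFrame   # gene_id, is_lti
    truth: pd.DataFrame
    config: SimulationConfig


def generate_dataset(
    topology: SpeciesTopology,
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
) -> Dataset:
    """Simulate a full dataset of ``cfg.n_genes`` genes.

    The number of LTI genes is fixed at ``round(n_genes * lti_fraction)``
    and their identities are drawn uniformly.  Dropout removes each species
    independently with its configured probability (genes that violate the
    downstream minimum-composition rule are still emitted — catching them is
    the pipeline's job).  With probability ``contaminant_rate`` a gene gets
    one contaminant taxon (never the anchor species).  Fully reproducible
    from ``cfg.seed``.

    When ``out_dir`` is given, writes one FASTA per gene, a labels TSV
    (gene_id, is_lti), the truth TSV and a key=value echo of the config.
    """
    root_ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(root_ss.spawn(1)[0])
    gene_streams = root_ss.spawn(cfg.n_genes)

    n_lti = int(round(cfg.n_genes * cfg.lti_fraction))
    lti_idx = set(master.choice(cfg.n_genes, size=n_lti, replace=False))

    genes: dict[str, CodonAlignment] = {}
    label_rows, truth_rows = [], []
    width = max(4, len(str(cfg.n_genes)))
    for g in range(cfg.n_genes):
        rng = np.random.default_rng(gene_streams[g])
        gene_id = f"g{g + 1:0{width}d}"
        gene_class = "lti" if g in lti_idx else "background"

        contaminant = None
        if rng.random() < cfg.contaminant_rate:
            candidates = [s for s in topology.taxa if s != ANCHOR_SPECIES]
            contaminant = candidates[rng.integers(len(candidates))]

        aln, truth = simulate_gene(topology, cfg, gene_class, rng,
                                   contaminant_taxon=contaminant)

        dropped = [
            sp for sp in topology.taxa
            if rng.random() < cfg.dropout_probs.get(sp, 0.0)
        ]
        keep = [sp for sp in aln.taxa if sp not in dropped]
        aln = aln.subset(keep)

        truth.update(gene_id=gene_id, dropped_taxa=";".join(dropped))
        genes[gene_id] = aln
        label_rows.append({"gene_id": gene_id, "is_lti": truth["is_lti"]})
        truth_rows.append(truth)

    labels = pd.DataFrame(label_rows)
    truth_df = pd.DataFrame(truth_rows)
    front = ["gene_id", "is_lti"]
    truth_df = truth_df[front + [c for c in truth_df.columns if c not in front]]
    ds = Dataset(genes=genes, labels=labels, truth=truth_df, config=cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gene_dir = out / "genes"
        gene_dir.mkdir(exist_ok=True)
        for gene_id, aln in genes.items():
            aln.write_fasta(gene_dir / f"{gene_id}.fasta")
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "config.txt", "w") as fh:
            for key, val in _flatten_config(cfg):
                fh.write(f"{key}={val}\n")
    return ds


def _flatten_config(cfg: SimulationConfig):
    for name in ("n_genes", "lti_fraction", "n_codons", "kappa",
                 "foreground_branch", "contaminant_rate",
                 "contaminant_stretch", "seed"):
        yield name, getattr(cfg, name)
    for br, t in sorted(cfg.branch_lengths.items()):
        yield f"branch_length.{br}", t
    for sp, p in sorted(cfg.dropout_probs.items()):
        yield f"dropout.{sp}", p
    for label, cls in (("background", cfg.background_classes),
                       ("lti", cfg.lti_classes)):
        for f in ("p0", "p1", "omega0", "omega2"):
            yield f"{label}.{f}", getattr(cls, f)


def neutral_config(cfg: SimulationConfig | None = None, **kwargs) -> SimulationConfig:
    """A copy of ``cfg`` with all positive selection removed (LTI genes use
    the background mixture) — the generative null of the branch-site test."""
    cfg = cfg or SimulationConfig(**kwargs)
    return replace(cfg, lti_classes=replace(cfg.lti_classes, omega2=1.0))


def expected_flux(params: BranchSiteParams, foreground: bool) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) substitution flux per codon per
    unit branch length, marginalised over site classes — the direct oracle
    for realized substitution counts in the simulator."""
    weights = params.class_proportions()
    bg, fg = params.class_omegas()
    omegas = fg if foreground else bg
    scale = params.normalizer()
    syn = nonsyn = 0.0
    for w, om in zip(weights, omegas):
        if w <= 0:
            continue
        Q = gy94_raw_Q(params.kappa, float(om), params.pi) / scale
        flux = params.pi[:, None] * Q
        syn += w * float(np.sum(np.where(IS_SYNONYMOUS, flux, 0.0)))
        nonsyn += w * float(
            np.sum(np.where(SINGLE_STEP_NONSYN, flux, 0.0))
        )
    return syn, nonsyn
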
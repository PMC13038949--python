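"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the five input classes a comparative
niche-evolution study consumes — an ultrametric chronogram, per-species
habitat-suitability rasters, occurrence records, trait tables, and
in-frame codon alignments — so every downstream analysis can be exercised
and calibrated without external data.

Each generator is a pure function of its inputs and a seed: identical
calls give identical outputs.  No global random state is touched.

Ground-truth parameters (niche optima, Mk rate, Brownian rate, omega) are
returned alongside the data and can be written to a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import molevol
from .trees import Phylogeny, write_newick

__all__ = [
    "SimConfig",
    "NicheParams",
    "OccurrenceSet",
    "TreeSimulationError",
    "simulate_tree",
    "simulate_landscape",
    "sample_occurrences",
    "simulate_trait",
    "simulate_codon_alignment",
    "write_dataset",
]


class TreeSimulationError(RuntimeError):
    """Birth-death simulation failed to reach the target tip count."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic study system.

    Defaults sketch a desk-scale temperate plant radiation: a modest clade
    simulated under a birth-death process with mild extinction, 19
    environmental layers (as in standard bioclimatic variable sets),
    Gaussian niche responses, a binary growth-form-like character, and
    plastid-like coding genes of 300 codons evolving under purifying
    selection (omega = 0.2) with transition bias kappa = 2.
    """

    seed: int = 0
    n_species: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.2
    grid_shape: tuple[int, int] = (40, 40)
    n_env_layers: int = 19
    bm_rate_niche: float = 0.05
    niche_breadth: float = 2.0
    n_occurrences: int = 200
    mk_states: int = 2
    mk_rate: float = 0.5
    bm_rate_trait: float = 1.0
    omega: float = 0.2
    kappa: float = 2.0
    n_codons: int = 300
    env_smooth_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.birth_rate <= self.death_rate:
            raise ValueError("birth_rate must exceed death_rate")
        for name in ("birth_rate", "death_rate", "bm_rate_niche", "bm_rate_trait",
                     "mk_rate", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        r, c = self.grid_shape
        if r * c < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.mk_states < 2:
            raise ValueError("mk_states must be >= 2")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be > 0")


@dataclass
class NicheParams:
    """Ground-truth Gaussian niche: per species, per axis optimum and breadth."""

    species: list[str]
    optima: np.ndarray  # (n_species, n_axes)
    breadth: np.ndarray  # (n_axes,)


@dataclass
class OccurrenceSet:
    """Integer cell coordinates of occurrence records for one species."""

    species: str
    cells: list[tuple[int, int]]


# ------------------------------------------------------------------ tree

def simulate_tree(config: SimConfig, max_attempts: int = 1000) -> Phylogeny:
    """Constant-rate birth-death tree conditioned on ``n_species`` tips.

    The process starts at the root split (two lineages) and runs until the
    (n+1)-th extant lineage would be born; that event is discarded and its
    time becomes the present, so under pure birth the root age is a sum of
    Exp(k * birth_rate) waits for k = 2..n.  Runs that go extinct are
    rejected and resimulated, up to ``max_attempts``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    b, d = config.birth_rate, config.death_rate
    for _ in range(max_attempts):
        result = _bd_once(rng, n, b, d)
        if result is not None:
            return result
    raise TreeSimulationError(
        f"birth-death simulation went extinct {max_attempts} times "
        f"(birth={b}, death={d}, n={n})"
    )


def _bd_once(rng: np.random.Generator, n: int, b: float, d: float) -> Phylogeny | None:
    # node bookkeeping: each lineage has a birth time; splits create children
    parent: list[int] = [-1]
    birth_time: list[float] = [0.0]
    children: list[list[int]] = [[]]

    def new_node(p: int, t: float) -> int:
        parent.append(p)
        birth_time.append(t)
        children.append([])
        children[p].append(len(parent) - 1)
        return len(parent) - 1

    t = 0.0
    root = 0
    extant = [new_node(root, 0.0), new_node(root, 0.0)]
    while True:
        k = len(extant)
        if k == 0:
            return None
        total = k * (b + d)
        t += rng.exponential(1.0 / total)
        target = extant[rng.integers(k)]
        if rng.random() < b / (b + d):
            if k + 1 > n:
                present = t  # discard the (n+1)-th birth; stop here
                break
            extant.remove(target)
            extant.append(new_node(target, t))
            extant.append(new_node(target, t))
        else:
            extant.remove(target)
            # dead lineage: marked by absence from `extant`

    return _build_pruned(parent, birth_time, children, extant, present, rng)


def _build_pruned(parent, birth_time, children, extant, present,
                  rng) -> Phylogeny | None:
    """Drop extinct lineages, suppress unifurcations, emit a Phylogeny."""
    n_raw = len(parent)
    keep = np.zeros(n_raw, dtype=bool)
    for tip in extant:
        v = tip
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = parent[v]
    # depth-first rebuild with unifurcation suppression
    tip_set = set(extant)

    def surviving_children(v: int) -> list[int]:
        return [c for c in children[v] if keep[c]]

    # find effective root: descend while only one surviving child and not a tip
    root = 0
    while root not in tip_set and len(surviving_children(root)) == 1:
        root = surviving_children(root)[0]
    if root in tip_set or len(surviving_children(root)) < 2:
        return None  # degenerate (should not happen with n >= 3)

    nodes: list[dict] = []  # {parent, length, children, tip}

    def split_time(v: int) -> float:
        # a lineage splits at most once; both raw children share a birth time
        return birth_time[children[v][0]]

    def build(v: int, top_time: float, my_parent: int) -> int:
        """v has >= 2 surviving children or is an extant tip; top_time is
        where the (suppression-merged) edge leading to v starts."""
        if v in tip_set:
            idx = len(nodes)
            nodes.append({"parent": my_parent, "length": present - top_time,
                          "children": [], "tip": True})
            return idx
        idx = len(nodes)
        nodes.append({"parent": my_parent, "length": split_time(v) - top_time,
                      "children": [], "tip": False})
        for c in surviving_children(v):
            # walk through unifurcations; the edge starts at c's birth
            w, start = c, birth_time[c]
            while w not in tip_set and len(surviving_children(w)) == 1:
                w = surviving_children(w)[0]
            ci = build(w, start, idx)
            nodes[idx]["children"].append(ci)
        return idx

    build(root, split_time(root), -1)  # root edge length 0 (no stem)

    # renumber: tips first (preorder appearance), then internals in post-order
    order_tips: list[int] = []
    order_int: list[int] = []

    def pre(v: int) -> None:
        if nodes[v]["tip"]:
            order_tips.append(v)
        for c in nodes[v]["children"]:
            pre(c)

    def post_int(v: int) -> None:
        for c in nodes[v]["children"]:
            post_int(c)
        if not nodes[v]["tip"]:
            order_int.append(v)

    pre(0)
    post_int(0)
    n_tips = len(order_tips)
    remap = {old: i for i, old in enumerate(order_tips)}
    remap.update({old: n_tips + i for i, old in enumerate(order_int)})
    n_nodes = len(nodes)
    parent_arr = np.full(n_nodes, -1, dtype=np.intp)
    lengths = np.zeros(n_nodes)
    kids: list[list[int]] = [[] for _ in range(n_nodes)]
    for old, new in remap.items():
        nd = nodes[old]
        lengths[new] = nd["length"]
        if nd["parent"] >= 0:
            parent_arr[new] = remap[nd["parent"]]
    for old, new in remap.items():
        for c in nodes[old]["children"]:
            kids[new].append(remap[c])
    for lst in kids:
        lst.sort()
    tip_labels = [f"sp{i + 1}" for i in range(n_tips)]
    tree = Phylogeny(parent=parent_arr, children=kids, edge_length=lengths,
                     tip_labels=tip_labels)
    tree.validate()
    return tree


# ------------------------------------------------------------- landscape

def _brownian_on_tree(tree: Phylogeny, rate: float, root_value: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Brownian values at every node; returns (n_nodes, n_axes)."""
    n_axes = root_value.size
    vals = np.zeros((tree.n_nodes, n_axes))
    vals[tree.root] = root_value
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        t = tree.edge_length[node]
        vals[node] = vals[p] + rng.normal(0.0, np.sqrt(max(rate * t, 0.0)), n_axes)
    return vals


def simulate_landscape(tree: Phylogeny, config: SimConfig):
    """Environmental layers, ground-truth niches, and suitability rasters.

    Layers are smoothed Gaussian random fields (white noise convolved with
    an isotropic kernel, then standardized), giving spatial autocorrelation
    like real bioclimatic surfaces.  Niche optima evolve along the tree by
    Brownian motion with rate ``bm_rate_niche`` from a root optimum at each
    layer's mean; suitability at a cell is the product over axes of
    Gaussian responses ``exp(-(env - mu)^2 / (2 sigma^2))``, rescaled per
    species so its maximum cell is 1 (a common positive rescaling, to
    which Schoener's D is invariant).

    Returns ``(env_layers, NicheParams, {species: suitability grid})``.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows, cols = config.grid_shape
    layers = []
    for _ in range(config.n_env_layers):
        field_ = gaussian_filter(rng.standard_normal((rows, cols)),
                                 sigma=config.env_smooth_sigma, mode="wrap")
        sd = field_.std()
        if sd > 0:
            field_ = (field_ - field_.mean()) / sd
        layers.append(field_)
    env = np.stack(layers)  # (n_axes, rows, cols)

    root_opt = env.mean(axis=(1, 2))
    optima_nodes = _brownian_on_tree(tree, config.bm_rate_niche, root_opt, rng)
    optima = optima_nodes[: tree.n_tips]
    sigma = np.full(config.n_env_layers, float(config.niche_breadth))

    grids: dict[str, np.ndarray] = {}
    for i, sp in enumerate(tree.tip_labels):
        # log suitability summed over axes; per-species max rescaling avoids
        # underflow with many axes and leaves overlap statistics unchanged
        logit = -((env - optima[i][:, None, None]) ** 2
                  / (2.0 * sigma[:, None, None] ** 2)).sum(axis=0)
        grids[sp] = np.exp(logit - logit.max())
    params = NicheParams(species=list(tree.tip_labels), optima=optima,
                         breadth=sigma)
    return env, params, grids


def sample_occurrences(grid: np.ndarray, n: int, seed: int,
                       species: str = "sp") -> OccurrenceSet:
    """Draw ``n`` occurrence cells with probability proportional to suitability."""
    total = grid.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"{species}: suitability grid has no positive mass")
    if n == 0:
        return OccurrenceSet(species=species, cells=[])
    rng = np.random.default_rng(seed)
    p = (grid / total).ravel()
    idx = rng.choice(p.size, size=n, p=p)
    rows, cols = np.unravel_index(idx, grid.shape)
    return OccurrenceSet(species=species,
                         cells=[(int(r), int(c)) for r, c in zip(rows, cols)])


# ----------------------------------------------------------------- traits

def simulate_trait(tree: Phylogeny, kind: str, config: SimConfig,
                   seed: int) -> np.ndarray:
    """Simulate one character on the tree.

    ``kind="continuous"``: Brownian motion with rate ``bm_rate_trait`` from
    root value 0.  ``kind="discrete"``: Mk1 with ``mk_states`` states,
    equal rates ``mk_rate`` and a uniform root state, simulated by drawing
    exponential waiting times along each branch.
    Returns one value per tip in ``tree.tip_labels`` order.
    """
    rng = np.random.default_rng(seed)
    if kind == "continuous":
        vals = _brownian_on_tree(tree, config.bm_rate_trait,
                                 np.zeros(1), rng)[:, 0]
        return vals[: tree.n_tips]
    if kind != "discrete":
        raise ValueError(f"unknown trait kind {kind!r}")
    k, q = config.mk_states, config.mk_rate
    state = np.empty(tree.n_nodes, dtype=np.intp)
    state[tree.root] = rng.integers(k)
    leave_rate = (k - 1) * q
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        s = state[p]
        remaining = float(tree.edge_length[node])
        if leave_rate > 0:
            while True:
                wait = rng.exponential(1.0 / leave_rate)
                if wait >= remaining:
                    break
                remaining -= wait
                s = (s + 1 + rng.integers(k - 1)) % k  # uniform among others
        state[node] = s
    return state[: tree.n_tips].copy()


# ------------------------------------------------------------------ codons

def _codon_rate_table(omega: float, kappa: float):
    """Per-codon substitution targets and rates under a GY94-style model.

    Rates: transversion 1, transition kappa, times omega when the change is
    nonsynonymous; changes to stop codons have rate 0.  The whole matrix is
    scaled so the expected number of substitutions per codon per unit
    branch length is 1 under uniform sense-codon frequencies.
    """
    sense = molevol.SENSE_CODONS
    code = molevol.GENETIC_CODE
    targets: dict[str, list[str]] = {}
    rates: dict[str, np.ndarray] = {}
    for codon in sense:
        tg, rt = [], []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt in molevol.STOP_CODONS:
                    continue
                r = kappa if molevol.is_transition(codon[pos], base) else 1.0
                if code[alt] != code[codon]:
                    r *= omega
                tg.append(alt)
                rt.append(r)
        targets[codon] = tg
        rates[codon] = np.array(rt)
    mean_rate = float(np.mean([rates[c].sum() for c in sense]))
    for codon in sense:
        rates[codon] = rates[codon] / mean_rate
    totals = {c: float(rates[c].sum()) for c in sense}
    return targets, rates, totals


def simulate_codon_alignment(tree: Phylogeny, config: SimConfig, seed: int,
                             gene: str = "gene1") -> molevol.CodonAlignment:
    """Codon alignment evolved along the tree under a GY94-style process.

    Branch lengths are in expected substitutions per codon (the rate
    matrix is normalized to 1 substitution/codon/unit time under uniform
    sense-codon frequencies).  Stop codons are never introduced and the
    root sequence contains none.  Substitutions are simulated exactly by
    Gillespie draws per codon site.
    """
    rng = np.random.default_rng(seed)
    targets, rates, totals = _codon_rate_table(config.omega, config.kappa)
    sense = molevol.SENSE_CODONS
    root = [sense[i] for i in rng.integers(len(sense), size=config.n_codons)]
    if sum(molevol._SYN_SITES[c] for c in root) <= 0:
        raise ValueError(
            f"{gene}: root sequence of {config.n_codons} codon(s) has zero "
            "synonymous sites; increase n_codons"
        )
    seqs: dict[int, list[str]] = {tree.root: root}
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        t = float(tree.edge_length[node])
        seq = list(seqs[p])
        if t > 0:
            for i in range(len(seq)):
                codon = seq[i]
                remaining = t
                while True:
                    tot = totals[codon]
                    wait = rng.exponential(1.0 / tot)
                    if wait >= remaining:
                        break
                    remaining -= wait
                    r = rates[codon]
                    codon = targets[codon][rng.choice(r.size, p=r / r.sum())]
                seq[i] = codon
        seqs[node] = seq
    records = [(lab, "".join(seqs[i])) for i, lab in enumerate(tree.tip_labels)]
    return molevol.CodonAlignment(gene=gene, records=records, pseudogene=False)


# -------------------------------------------------------------------- I/O

def write_raster_csv(path: Path, grid: np.ndarray) -> None:
    """CSV raster: first line "rows,cols", then comma-separated rows."""
    rows, cols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{rows},{cols}\n")
        for r in range(rows):
            fh.write(",".join(f"{v:.10g}" for v in grid[r]) + "\n")


def read_raster_csv(path: Path) -> np.ndarray:
    with open(path) as fh:
        rows, cols = (int(x) for x in fh.readline().split(","))
        grid = np.loadtxt(fh, delimiter=",", ndmin=2)
    if grid.shape != (rows, cols):
        raise ValueError(f"{path}: header says {(rows, cols)}, data is {grid.shape}")
    return grid


def write_dataset(out_dir: str | Path, config: SimConfig) -> dict:
    """Generate one full synthetic study dataset and write it to disk.

    Writes the chronogram (Newick), per-species suitability rasters (CSV),
    occurrences (CSV), a trait table with one continuous and one discrete
    character (CSV), one codon alignment per species set (FASTA), and a
    JSON sidecar with the ground truth.  Returns the ground-truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")

    env, params, grids = simulate_landscape(tree, config)
    (out / "rasters").mkdir(exist_ok=True)
    for sp, grid in grids.items():
        write_raster_csv(out / "rasters" / f"{sp}.csv", grid)

    occ_lines = ["species,row,col"]
    for i, sp in enumerate(tree.tip_labels):
        occ = sample_occurrences(grids[sp], config.n_occurrences,
                                 seed=config.seed + 100 + i, species=sp)
        occ_lines += [f"{sp},{r},{c}" for r, c in occ.cells]
    (out / "occurrences.csv").write_text("\n".join(occ_lines) + "\n")

    cont = simulate_trait(tree, "continuous", config, seed=config.seed + 200)
    disc = simulate_trait(tree, "discrete", config, seed=config.seed + 201)
    lines = ["species,trait_cont,trait_disc"]
    lines += [f"{sp},{cont[i]:.10g},{int(disc[i])}"
              for i, sp in enumerate(tree.tip_labels)]
    (out / "traits.csv").write_text("\n".join(lines) + "\n")

    aln = simulate_codon_alignment(tree, config, seed=config.seed + 300)
    with open(out / "gene1.fasta", "w") as fh:
        for lab, seq in aln.records:
            fh.write(f">{lab}\n{seq}\n")

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "niche_optima": {sp: params.optima[i].tolist()
                         for i, sp in enumerate(tree.tip_labels)},
        "niche_breadth": params.breadth.tolist(),
        "mk_rate": config.mk_rate,
        "bm_rate_trait": config.bm_rate_trait,
        "omega": config.omega,
        "kappa": config.kappa,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
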
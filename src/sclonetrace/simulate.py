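"""Synthetic multi-site single-cell tumor patients with known clonal truth.

The generator emulates the data a multi-region sampling design produces:
matched adjacent-normal tissue (N), primary tumor regions (PT_R1..), and
lymph-node / liver / omentum metastases (LyM, LM, OM), each a mixture of
clones from a rooted clone tree. Tumor clones carry

* a truncal homoplasmic mitochondrial mutation shared by every tumor cell,
* clone-private heteroplasmic mitochondrial mutations (inherited along the
  tree, so a metastatic clone carries its ancestors' mutations plus extras),
* arm-level copy-number events that dose expression multiplicatively
  (copy / 2), and
* optionally a nuclear driver mutation linked to an expression program
  (a set of genes whose mean shifts by 2**log2_shift in program-on cells).

UMI counts are negative binomial around per-gene log-normal baselines;
mitochondrial site depths are Poisson, with alt reads binomial at the
clone's heteroplasmy; a configurable fraction of cells is injected as
QC failures (low gene detection, or gene-identity scrambling that breaks
cell-cell correlation). Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._genome import DEFAULT_CHROM_LENGTHS, MT_GENOME_LENGTH, place_genes

__all__ = [
    "CnvEvent", "MitoSite", "DriverSpec", "SimulationConfig", "GroundTruth",
    "SyntheticDataset", "SimulationConfigError", "default_config",
    "simulate_patient", "simulate_wgs_windows",
]

NORMAL_CLONE = "normal"

#: read-depth below which a mitochondrial site state is undeterminable
MIN_DETERMINABLE_DEPTH = 9


class SimulationConfigError(ValueError):
    """A simulation config violates one of its invariants."""


@dataclass(frozen=True)
class CnvEvent:
    chrom: str
    start: int
    end: int
    copy_number: int  # one of {1, 2, 3, 4}


@dataclass(frozen=True)
class MitoSite:
    position: int          # 1-based on the circular mitochondrial genome
    heteroplasmy: float    # mutant allele fraction in [0, 1]


@dataclass(frozen=True)
class DriverSpec:
    """One nuclear driver locus and its linked expression program."""
    locus: str = "TP53"
    states: dict[str, str] = field(default_factory=dict)  # clone -> WT/HET_MUT/HOM_MUT
    program_genes: tuple[int, ...] = ()    # gene indices whose mean shifts
    log2_shift: float = 2.0
    program_penetrance: dict[str, float] = field(default_factory=dict)
    detection_rate: float = 0.9            # per-cell genotyping success
    #: program genes are actively transcribed genes; their baseline mean is
    #: floored here so the planted shift is a property of expressed genes
    min_base_mean: float = 5.0


@dataclass
class SimulationConfig:
    """Full description of one synthetic patient.

    ``sites`` maps ordered site labels (N, PT_R*, LyM, LM, OM) to cell
    counts; ``site_composition`` gives each site's clone mixture (clone
    label -> fraction, "normal" allowed). ``clone_tree`` maps each tumor
    clone to its parent (root/precursor clone -> None). CNV events and
    private mitochondrial sites are inherited root-to-leaf; a child's event
    overrides an ancestor's on overlap.
    """
    sites: dict[str, int]
    site_composition: dict[str, dict[str, float]]
    clone_tree: dict[str, str | None]
    n_genes: int = 2000
    truncal_mito_site: int = 13368
    private_mito_sites: dict[str, list[MitoSite]] = field(default_factory=dict)
    cnv_events: dict[str, list[CnvEvent]] = field(default_factory=dict)
    mean_site_depth: float = 50.0
    undetermined_fraction_target: float | None = None
    lowq_cell_fraction: float = 0.0
    driver: DriverSpec = field(default_factory=DriverSpec)
    dispersion: float = 0.2                # NB: var = m + dispersion * m^2
    base_log_mean: float = 1.5             # log-normal baseline, natural log
    base_log_sigma: float = 2.4
    library_size_sigma: float = 0.2
    base_error_rate: float = 0.002         # mito sequencing error
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.undetermined_fraction_target is not None:
            self.mean_site_depth = _depth_for_undetermined_fraction(
                self.undetermined_fraction_target)
        validate_config(self)

    @property
    def clones(self) -> list[str]:
        return list(self.clone_tree)

    @property
    def n_clones(self) -> int:
        return len(self.clone_tree)

    @property
    def expected_undetermined_fraction(self) -> float:
        """P(depth < 9) under the Poisson depth model: the closed-form
        expected fraction of undeterminable cell-site pairs."""
        return float(stats.poisson.cdf(MIN_DETERMINABLE_DEPTH - 1,
                                       self.mean_site_depth))

    def ancestry(self, clone: str) -> list[str]:
        """Root-to-clone path in the clone tree."""
        path, cur = [], clone
        while cur is not None:
            path.append(cur)
            cur = self.clone_tree[cur]
        return path[::-1]


def _depth_for_undetermined_fraction(target: float) -> float:
    from scipy.optimize import brentq
    if not 0 < target < 1:
        raise SimulationConfigError(
            f"undetermined_fraction_target must lie in (0, 1), got {target}")
    f = lambda lam: stats.poisson.cdf(MIN_DETERMINABLE_DEPTH - 1, lam) - target
    return float(brentq(f, 1e-6, 1e4))


_METASTATIC_PREFIXES = ("LyM", "LM", "OM")


def site_type(label: str) -> str:
    """Classify a site label as 'normal', 'primary' or 'metastasis'."""
    if label.startswith(_METASTATIC_PREFIXES):
        return "metastasis"
    if label.startswith("PT"):
        return "primary"
    return "normal"


def validate_config(cfg: SimulationConfig) -> None:
    """Raise :class:`SimulationConfigError` naming the violated invariant."""
    if not cfg.sites:
        raise SimulationConfigError("sites: at least one site is required")
    if any(n <= 0 for n in cfg.sites.values()):
        raise SimulationConfigError("sites: zero or negative cell count requested")

    roots = [c for c, p in cfg.clone_tree.items() if p is None]
    if len(roots) != 1:
        raise SimulationConfigError(
            f"clone_tree: expected exactly one root, found {len(roots)}")
    for clone, parent in cfg.clone_tree.items():
        if parent is not None and parent not in cfg.clone_tree:
            raise SimulationConfigError(
                f"clone_tree: parent {parent!r} of {clone!r} is not a clone")
        seen, cur = {clone}, parent
        while cur is not None:
            if cur in seen:
                raise SimulationConfigError(f"clone_tree: cycle through {cur!r}")
            seen.add(cur)
            cur = cfg.clone_tree[cur]

    if not 1 <= cfg.truncal_mito_site <= MT_GENOME_LENGTH:
        raise SimulationConfigError(
            f"truncal_mito_site {cfg.truncal_mito_site} outside "
            f"1..{MT_GENOME_LENGTH}")
    for clone, sites in cfg.private_mito_sites.items():
        if clone not in cfg.clone_tree:
            raise SimulationConfigError(
                f"private_mito_sites: unknown clone {clone!r}")
        for s in sites:
            if not 0.0 <= s.heteroplasmy <= 1.0:
                raise SimulationConfigError(
                    f"heteroplasmy {s.heteroplasmy} at site {s.position} "
                    "outside [0, 1]")
            if not 1 <= s.position <= MT_GENOME_LENGTH:
                raise SimulationConfigError(
                    f"mitochondrial position {s.position} outside "
                    f"1..{MT_GENOME_LENGTH}")

    for clone, events in cfg.cnv_events.items():
        if clone not in cfg.clone_tree:
            raise SimulationConfigError(f"cnv_events: unknown clone {clone!r}")
        for ev in events:
            if ev.chrom not in cfg.chrom_lengths:
                raise SimulationConfigError(
                    f"cnv_events: unknown chromosome {ev.chrom!r}")
            if not (0 <= ev.start < ev.end <= cfg.chrom_lengths[ev.chrom]):
                raise SimulationConfigError(
                    f"cnv_events: interval {ev.chrom}:{ev.start}-{ev.end} "
                    "outside declared chromosome length")
            if ev.copy_number not in (1, 2, 3, 4):
                raise SimulationConfigError(
                    f"cnv_events: copy_number {ev.copy_number} not in 1..4")

    for label in cfg.sites:
        comp = cfg.site_composition.get(label)
        if comp is None:
            raise SimulationConfigError(
                f"site_composition: missing mixture for site {label!r}")
        for clone in comp:
            if clone != NORMAL_CLONE and clone not in cfg.clone_tree:
                raise SimulationConfigError(
                    f"site_composition[{label!r}]: unknown clone {clone!r}")
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"site_composition[{label!r}]: fractions do not sum to 1")

    if any(site_type(s) == "metastasis" for s in cfg.sites) and cfg.n_clones < 2:
        raise SimulationConfigError(
            "n_clones must be >= 2 when a metastatic site is declared")
    if not 0.0 <= cfg.lowq_cell_fraction < 1.0:
        raise SimulationConfigError(
            f"lowq_cell_fraction {cfg.lowq_cell_fraction} outside [0, 1)")
    if cfg.dispersion < 0:
        raise SimulationConfigError("dispersion must be nonnegative")


@dataclass
class GroundTruth:
    """The simulator's answer key for parameter-recovery tests."""
    cells: pd.DataFrame          # cell_id idx: site, clone, qc_fail, qc_fail_mode,
                                 # driver_state, program_on
    clone_heteroplasmy: pd.DataFrame   # clone x mito position -> fraction
    clone_mito_genotype: pd.DataFrame  # clone x mito position -> WT/HET/HOM
    clone_copy: pd.DataFrame     # clone x gene -> integer copy number
    metastasis_sources: dict[str, str]  # met site label -> source clone in PT
    clone_tree: dict[str, str | None]


@dataclass
class SyntheticDataset:
    """All tables of a simulated patient plus the ground truth."""
    adata: ad.AnnData                   # cells x genes UMI counts; obs: site
    allele_counts: pd.DataFrame         # cell_id, pos, ref_count, alt_count
    driver_genotypes: pd.DataFrame      # cell_id, locus, state
    truth: GroundTruth

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference synthetic patient: 300 cells over N / two primary-tumor
    regions / lymph-node and liver metastases, three tumor clones.

    C1 is the truncal (precursor) clone; C2 and C3 are its children. The
    truncal site 13368 is homoplasmic in every tumor cell; C2 privately
    carries a heteroplasmic (0.5) mutation at 2897, C3 a homoplasmic one at
    10396 — the three heteroplasmy levels {0, 0.5, 1.0}. LyM is seeded from
    C2, LM from C3. Arm-scale CNVs: +7 truncal, chr18 loss in C2, +20 in
    C3. C3 additionally carries a driver mutation linked to a 20-gene
    4-fold expression program.
    """
    chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    n_genes = overrides.pop("n_genes", 2000)
    # 20 program genes on chr5 (no CNV there, so dosage and program don't mix)
    var = place_genes(n_genes, chrom_lengths)
    chr5 = np.flatnonzero((var["chrom"] == "5").to_numpy())
    program = tuple(int(i) for i in chr5[:20])
    cfg = dict(
        sites={"N": 60, "PT_R1": 80, "PT_R2": 80, "LyM": 40, "LM": 40},
        site_composition={
            "N": {NORMAL_CLONE: 1.0},
            "PT_R1": {"C1": 0.5, "C2": 0.5},
            "PT_R2": {"C1": 0.5, "C3": 0.5},
            "LyM": {"C2": 1.0},
            "LM": {"C3": 1.0},
        },
        clone_tree={"C1": None, "C2": "C1", "C3": "C1"},
        n_genes=n_genes,
        truncal_mito_site=13368,
        private_mito_sites={
            "C2": [MitoSite(2897, 0.5)],
            "C3": [MitoSite(10396, 1.0)],
        },
        cnv_events={
            "C1": [CnvEvent("7", 0, chrom_lengths["7"], 3)],
            "C2": [CnvEvent("18", 0, chrom_lengths["18"], 1)],
            "C3": [CnvEvent("20", 0, chrom_lengths["20"], 3)],
        },
        mean_site_depth=50.0,
        lowq_cell_fraction=0.1,
        driver=DriverSpec(locus="TP53", states={"C3": "HET_MUT"},
                          program_genes=program, log2_shift=2.0),
        chrom_lengths=chrom_lengths,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _clone_copy_profiles(cfg: SimulationConfig,
                         var: pd.DataFrame) -> pd.DataFrame:
    """Per-clone integer copy number per gene, events inherited along the
    tree (child overrides ancestor on overlap)."""
    profiles = {NORMAL_CLONE: np.full(len(var), 2, dtype=int)}
    chrom = var["chrom"].to_numpy()
    start = var["start"].to_numpy()
    for clone in cfg.clones:
        copy = np.full(len(var), 2, dtype=int)
        for anc in cfg.ancestry(clone):
            for ev in cfg.cnv_events.get(anc, []):
                mask = (chrom == ev.chrom) & (start >= ev.start) & (start < ev.end)
                copy[mask] = ev.copy_number
        profiles[clone] = copy
    return pd.DataFrame(profiles, index=var.index).T


def _clone_heteroplasmy(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-clone mutant allele fraction per mitochondrial site (inherited)."""
    positions = {cfg.truncal_mito_site}
    for sites in cfg.private_mito_sites.values():
        positions.update(s.position for s in sites)
    positions = sorted(positions)
    rows = {NORMAL_CLONE: {p: 0.0 for p in positions}}
    for clone in cfg.clones:
        h = {p: 0.0 for p in positions}
        h[cfg.truncal_mito_site] = 1.0
        for anc in cfg.ancestry(clone):
            for s in cfg.private_mito_sites.get(anc, []):
                h[s.position] = s.heteroplasmy
        rows[clone] = h
    return pd.DataFrame(rows).T[positions]


def heteroplasmy_to_state(h: float) -> str:
    """Expected determined-state call for a clone-level heteroplasmy."""
    if h <= 0.05:
        return "WT"
    if h >= 0.95:
        return "HOM"
    return "HET"


def simulate_patient(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic patient from ``config`` (fully seed-deterministic).

    Returns a :class:`SyntheticDataset` whose AnnData holds raw UMI counts
    (cells x genes, CSR), with site labels in ``obs`` and gene coordinates
    in ``var``, alongside the mitochondrial allele-count table, the per-cell
    driver genotype table and the ground truth.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)

    var = place_genes(config.n_genes, config.chrom_lengths)
    clone_copy = _clone_copy_profiles(config, var)
    clone_h = _clone_heteroplasmy(config)
    positions = clone_h.columns.to_numpy()

    base_mean = rng.lognormal(config.base_log_mean, config.base_log_sigma,
                              size=config.n_genes)
    if config.driver.program_genes:
        idx = np.asarray(config.driver.program_genes, dtype=int)
        base_mean[idx] = np.maximum(base_mean[idx], config.driver.min_base_mean)

    cells = []
    for label, n in config.sites.items():
        comp = config.site_composition[label]
        clones = list(comp)
        draw = rng.choice(len(clones), size=n, p=[comp[c] for c in clones])
        for i in range(n):
            cells.append((f"{label}_c{i:04d}", label, clones[draw[i]]))
    cell_df = pd.DataFrame(cells, columns=["cell_id", "site", "clone"]
                           ).set_index("cell_id")
    n_cells = len(cell_df)

    # --- driver program assignment -------------------------------------
    states = pd.Series(
        [config.driver.states.get(c, "WT") for c in cell_df["clone"]],
        index=cell_df.index)
    penetrance = pd.Series(
        [config.driver.program_penetrance.get(c, 1.0)
         for c in cell_df["clone"]], index=cell_df.index)
    mutant = states.isin(["HET_MUT", "HOM_MUT"]).to_numpy()
    program_on = mutant & (rng.random(n_cells) < penetrance.to_numpy())

    # --- expression counts ----------------------------------------------
    lib = rng.lognormal(0.0, config.library_size_sigma, size=n_cells)
    program_idx = np.asarray(config.driver.program_genes, dtype=int)
    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    disp = config.dispersion
    for i, (cell, row) in enumerate(cell_df.iterrows()):
        m = base_mean * (clone_copy.loc[row["clone"]].to_numpy() / 2.0) * lib[i]
        if program_on[i] and program_idx.size:
            m = m.copy()
            m[program_idx] *= 2.0 ** config.driver.log2_shift
        if disp > 0:
            r = 1.0 / disp
            counts[i] = rng.negative_binomial(r, r / (r + m))
        else:
            counts[i] = rng.poisson(m)

    # --- QC-failure injection -------------------------------------------
    qc_fail = np.zeros(n_cells, dtype=bool)
    fail_mode = np.array(["none"] * n_cells, dtype=object)
    n_lowq = int(round(config.lowq_cell_fraction * n_cells))
    if n_lowq:
        chosen = rng.choice(n_cells, size=n_lowq, replace=False)
        half = n_lowq // 2
        for j, idx in enumerate(chosen):
            qc_fail[idx] = True
            if j < n_lowq - half:
                # keep a few hundred random genes: detection falls below 1000
                keep = rng.choice(config.n_genes,
                                  size=min(600, config.n_genes), replace=False)
                dropped = np.ones(config.n_genes, dtype=bool)
                dropped[keep] = False
                counts[idx, dropped] = 0
                fail_mode[idx] = "low_genes"
            else:
                # scramble gene identities: detection stays, correlation dies
                counts[idx] = counts[idx][rng.permutation(config.n_genes)]
                fail_mode[idx] = "scrambled"

    # --- mitochondrial allele counts -------------------------------------
    h_per_cell = clone_h.loc[cell_df["clone"]].to_numpy()      # cells x sites
    depth = rng.poisson(config.mean_site_depth,
                        size=(n_cells, len(positions)))
    err = config.base_error_rate
    p_alt = np.clip(h_per_cell * (1 - err) + (1 - h_per_cell) * err, 0.0, 1.0)
    alt = rng.binomial(depth, p_alt)
    allele_counts = pd.DataFrame({
        "cell_id": np.repeat(cell_df.index.to_numpy(), len(positions)),
        "pos": np.tile(positions, n_cells),
        "ref_count": (depth - alt).ravel(),
        "alt_count": alt.ravel(),
    })

    # --- per-cell driver genotype table (Sanger-like, with dropouts) ------
    detected = rng.random(n_cells) < config.driver.detection_rate
    driver_genotypes = pd.DataFrame({
        "cell_id": cell_df.index,
        "locus": config.driver.locus,
        "state": np.where(detected, states.to_numpy(), "undetected"),
    })

    # --- assemble ---------------------------------------------------------
    obs = cell_df[["site"]].copy()
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var.copy())

    truth_cells = cell_df.copy()
    truth_cells["qc_fail"] = qc_fail
    truth_cells["qc_fail_mode"] = fail_mode
    truth_cells["driver_state"] = states
    truth_cells["program_on"] = program_on

    genotype = clone_h.map(heteroplasmy_to_state)
    truth = GroundTruth(
        cells=truth_cells,
        clone_heteroplasmy=clone_h,
        clone_mito_genotype=genotype,
        clone_copy=clone_copy,
        metastasis_sources=_metastasis_sources(config),
        clone_tree=dict(config.clone_tree),
    )
    return SyntheticDataset(adata=adata, allele_counts=allele_counts,
                            driver_genotypes=driver_genotypes, truth=truth)


def _metastasis_sources(cfg: SimulationConfig) -> dict[str, str]:
    """True source clone (in a primary region) of each metastatic site:
    the nearest ancestor-or-self of the site's dominant clone that is
    present in any primary-tumor mixture."""
    primary_clones = set()
    for label, comp in cfg.site_composition.items():
        if site_type(label) == "primary":
            primary_clones.update(c for c, f in comp.items()
                                  if f > 0 and c != NORMAL_CLONE)
    sources = {}
    for label, comp in cfg.site_composition.items():
        if site_type(label) != "metastasis":
            continue
        tumor = {c: f for c, f in comp.items() if c != NORMAL_CLONE}
        dominant = max(sorted(tumor), key=lambda c: tumor[c])
        source = None
        for anc in reversed(cfg.ancestry(dominant)):   # self, parent, ...
            if anc in primary_clones:
                source = anc
                break
        sources[label] = source if source is not None else cfg.ancestry(dominant)[0]
    return sources


def simulate_wgs_windows(config: SimulationConfig,
                         total_reads: int = 2_000_000,
                         window_size: int = 10_000_000,
                         rng: np.random.Generator | None = None,
                         ) -> pd.DataFrame:
    """Bulk WGS read counts per 10-Mb window for each sampled site.

    Reads fall into windows proportionally to window length times the
    site's clone-mixture-averaged copy number, with Poisson counting noise.
    Returns a long table (sample, chrom, start, end, count) suitable for
    :func:`sclonetrace.cnv.wgs_window_ratios`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    windows = []
    for chrom, ln in config.chrom_lengths.items():
        for s in range(0, ln, window_size):
            windows.append((chrom, s, min(s + window_size, ln)))
    wdf = pd.DataFrame(windows, columns=["chrom", "start", "end"])

    # mixture-averaged copy number per window per site
    rows = []
    for label in config.sites:
        comp = config.site_composition[label]
        weight = np.zeros(len(wdf))
        for clone, frac in comp.items():
            copy = np.full(len(wdf), 2.0)
            if clone != NORMAL_CLONE:
                for anc in config.ancestry(clone):
                    for ev in config.cnv_events.get(anc, []):
                        m = ((wdf["chrom"] == ev.chrom)
                             & (wdf["start"] < ev.end)
                             & (wdf["end"] > ev.start)).to_numpy()
                        copy[m] = ev.copy_number
            weight += frac * copy
        lam = weight * (wdf["end"] - wdf["start"]).to_numpy()
        lam = lam / lam.sum() * total_reads
        counts = rng.poisson(lam)
        out = wdf.copy()
        out.insert(0, "sample", label)
        out["count"] = counts
        rows.append(out)
    return pd.concat(rows, ignore_index=True)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON-serializable form of a config (inverse of :func:`config_from_dict`)."""
    d = dataclasses.asdict(cfg)
    d["private_mito_sites"] = {
        c: [[s.position, s.heteroplasmy] for s in v]
        for c, v in cfg.private_mito_sites.items()}
    d["cnv_events"] = {
        c: [[e.chrom, e.start, e.end, e.copy_number] for e in v]
        for c, v in cfg.cnv_events.items()}
    d["driver"] = dataclasses.asdict(cfg.driver)
    d["driver"]["program_genes"] = list(cfg.driver.program_genes)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["private_mito_sites"] = {
        c: [MitoSite(int(p), float(h)) for p, h in v]
        for c, v in d.get("private_mito_sites", {}).items()}
    d["cnv_events"] = {
        c: [CnvEvent(str(ch), int(s), int(e), int(cn)) for ch, s, e, cn in v]
        for c, v in d.get("cnv_events", {}).items()}
    if "driver" in d:
        drv = dict(d["driver"])
        drv["program_genes"] = tuple(int(i) for i in drv.get("program_genes", ()))
        d["driver"] = DriverSpec(**drv)
    return SimulationConfig(**d)
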
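"""Synthetic cortex generator with ground-truth annotations.

Emulates the statistical structure of a multi-animal in situ sequencing
study of the mouse cortex: littermate pairs split into a control and an
enucleated (perturbed) condition, a 1D mediolateral ribbon of cortical
areas per coronal slice, a hierarchy of excitatory H2/H3 types plus
inhibitory types, negative-binomial marker-panel counts with per-litter
effects, Dirichlet brain-to-brain compositional variability, an optional
perturbation that shifts one area's composition toward target areas, and
optional segmentation doublets that merge spatially adjacent cells.

Every quantity the downstream analyses estimate (type labels, area
compositions, module partition, shift direction) is returned as explicit
ground truth, so each pipeline stage can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .core import CellTable, PanelSpec

#: excitatory subclass names used for default taxonomies (cycled if n_h2 > 9)
H2_NAMES = ("L2/3 IT", "L4/5 IT", "L5 IT", "L6 IT", "L5 ET",
            "L6 CT", "NP", "Car3", "L6b")
INHIBITORY_NAMES = ("Pvalb", "Sst", "Vip", "Lamp5", "Sncg", "Meis2")

#: real marker-panel gene names used to label the first filler genes
_PANEL_GENES = (
    "Cux2", "Fezf2", "Foxp2", "Rorb", "Tshz2", "Slc30a3", "Tenm3", "Rspo1",
    "Cdh13", "Calb1", "Calb2", "Pcp4", "Rprm", "Crym", "Cplx3", "Ctgf",
    "Nr4a2", "Synpr", "Trh", "Deptor", "Marcksl1", "Lhx2", "Bhlhe22",
    "Cdh12", "Nnat", "Igfbp4", "Ncald", "Pou3f1", "Rasgrf2", "Scnn1a",
)


@dataclass(frozen=True)
class AreaSpec:
    """One cortical area: identity, module membership, geometry, composition.

    ``composition`` is the baseline probability vector over excitatory H3
    types; ``width_um`` is the mediolateral extent occupied on every slice
    (areas are laid out contiguously in list order).
    """

    name: str
    module: str
    composition: tuple[float, ...]
    width_um: float = 540.0

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if (comp < 0).any():
            raise ValueError(f"area {self.name}: negative composition entry")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(f"area {self.name}: composition must sum to 1")
        if self.width_um <= 0:
            raise ValueError(f"area {self.name}: non-positive width")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults describe the emulated study design: 4 littermate pairs
    (one control and one perturbed brain each), 3 coronal slices per
    brain, 12 areas grouped into 3 modules, 9 excitatory H2 types with 3
    H3 types each, 4 inhibitory types, and a 104-gene panel read out with
    negative-binomial noise at a depth of roughly 80 reads per cell.
    """

    n_litters: int = 4
    conditions: tuple[str, str] = ("control", "enucleated")
    n_slices: int = 3
    areas: list[AreaSpec] | None = None
    n_h2: int = 9
    h3_per_h2: int = 3
    n_inhibitory: int = 4
    n_genes: int = 104
    nb_dispersion: float = 0.5          # NB variance = mu + dispersion * mu^2
    depth_means: tuple[float, ...] | None = None
    depth_sd: float = 0.08
    litter_effect_sd: float = 0.1       # sd of per-litter log-normal gene factor
    inhibitory_fraction: float = 0.25
    dirichlet_conc: float = 2000.0      # brain-level Dirichlet concentration; inf disables
    cells_per_um: float = 1.5           # linear density along the mediolateral axis
    cortex_thickness_um: float = 1000.0
    doublet_rate: float = 0.0
    shift_weight: float = 0.0           # lambda: perturbed-condition composition shift
    shift_source: str | None = None
    shift_targets: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.areas is None:
            self.areas = default_areas(n_h2=self.n_h2,
                                       h3_per_h2=self.h3_per_h2)
        if self.depth_means is None:
            self.depth_means = tuple(
                np.round(np.linspace(0.2, 0.9, self.n_h2), 4))
        self.validate()

    # -- derived taxonomy -------------------------------------------------
    @property
    def n_h3(self) -> int:
        return self.n_h2 * self.h3_per_h2

    @property
    def h2_names(self) -> list[str]:
        base = [H2_NAMES[i % len(H2_NAMES)] for i in range(self.n_h2)]
        if self.n_h2 <= len(H2_NAMES):
            return base
        return [f"{n}_{i // len(H2_NAMES)}" if i >= len(H2_NAMES) else n
                for i, n in enumerate(base)]

    @property
    def h3_names(self) -> list[str]:
        return [f"{h2} {j + 1}" for h2 in self.h2_names
                for j in range(self.h3_per_h2)]

    @property
    def inhibitory_names(self) -> list[str]:
        return [INHIBITORY_NAMES[i % len(INHIBITORY_NAMES)]
                for i in range(self.n_inhibitory)]

    @property
    def area_names(self) -> list[str]:
        return [a.name for a in self.areas]

    @property
    def modules(self) -> dict[str, str]:
        return {a.name: a.module for a in self.areas}

    def validate(self) -> None:
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if not (0 <= self.shift_weight <= 1):
            raise ValueError("shift_weight must lie in [0, 1]")
        if not (0 <= self.inhibitory_fraction < 1):
            raise ValueError("inhibitory_fraction must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if len(self.depth_means) != self.n_h2:
            raise ValueError("depth_means must have one entry per H2 type")
        names = self.area_names
        if len(set(names)) != len(names):
            raise ValueError("area names must be unique")
        for a in self.areas:
            if len(a.composition) != self.n_h3:
                raise ValueError(
                    f"area {a.name}: composition length {len(a.composition)}"
                    f" != n_h3 {self.n_h3}")
        if self.shift_weight > 0 or self.shift_source is not None:
            if self.shift_source not in names:
                raise ValueError(f"unknown shift_source {self.shift_source!r}")
            if not self.shift_targets:
                raise ValueError("shift_targets required when shifting")
            for t in self.shift_targets:
                if t not in names:
                    raise ValueError(f"unknown shift target {t!r}")

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def plain(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, (list, tuple)):
                return [plain(i) for i in o]
            if isinstance(o, dict):
                return {k: plain(v) for k, v in o.items()}
            return o

        d = asdict(self)
        d["areas"] = [asdict(a) for a in self.areas]
        Path(path).write_text(yaml.safe_dump(plain(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("areas"):
            d["areas"] = [AreaSpec(name=a["name"], module=a["module"],
                                   composition=tuple(a["composition"]),
                                   width_um=a.get("width_um", 540.0))
                          for a in d["areas"]]
        for key in ("conditions", "depth_means", "shift_targets"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generative truth for one simulated dataset."""

    labels: pd.DataFrame            # index cell_id: true_h1/h2/h3, is_doublet
    area_composition: dict          # (condition, area) -> H3 probability vector
    modules: dict                   # area -> module id
    h3_names: list[str]
    h2_names: list[str]
    inhibitory_names: list[str]
    shift_source: str | None
    shift_targets: tuple[str, ...] | None
    shift_weight: float

    def apply_labels(self, cells: CellTable) -> None:
        """Copy true type labels into ``cells.obs`` (in place)."""
        lab = self.labels.loc[cells.obs["cell_id"]]
        for col in ("h1", "h2", "h3"):
            cells.obs[col] = lab[f"true_{col}"].to_numpy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modules": self.modules,
            "h3_names": self.h3_names,
            "h2_names": self.h2_names,
            "inhibitory_names": self.inhibitory_names,
            "shift_source": self.shift_source,
            "shift_targets": list(self.shift_targets or ()),
            "shift_weight": self.shift_weight,
            "area_composition": {
                f"{cond}|{area}": [float(x) for x in comp]
                for (cond, area), comp in self.area_composition.items()},
            "n_doublets": int(self.labels["is_doublet"].sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ----------------------------------------------------------------------
# Default study layout
# ----------------------------------------------------------------------

#: default area names per module (CCF-flavoured acronyms)
_DEFAULT_AREAS = {
    "visual": ("VISp", "VISl", "VISpm", "VISam"),
    "somatomotor": ("SSp", "SSs", "MOp", "MOs"),
    "medial": ("RSPd", "RSPv", "ACAd", "PL"),
}


def default_areas(n_areas: int = 12, n_modules: int = 3, n_h2: int = 9,
                  h3_per_h2: int = 3, width_um: float = 540.0,
                  tilt: float = 0.5, background: float = 0.15,
                  ) -> list[AreaSpec]:
    """Planted area layout: contiguous modules with circulant area tilts.

    Each module owns a block of H2 types (hence a block of H3 types).
    Areas within a module concentrate their composition on the module
    block, with a cosine tilt of amplitude ``tilt`` whose phase rotates
    across the module's areas, so sibling areas are similar but
    discriminable; areas from different modules have nearly disjoint
    compositional supports.
    """
    n_h3 = n_h2 * h3_per_h2
    module_names = list(_DEFAULT_AREAS)
    areas: list[AreaSpec] = []
    for i in range(n_areas):
        m = i * n_modules // n_areas
        members = [j for j in range(n_areas) if j * n_modules // n_areas == m]
        j_in = members.index(i)
        h2_lo = m * n_h2 // n_modules
        h2_hi = (m + 1) * n_h2 // n_modules
        block = [t for t in range(n_h3)
                 if h2_lo <= t // h3_per_h2 < h2_hi]
        w = np.full(n_h3, background)
        phase = 2 * np.pi * j_in / max(len(members), 1)
        for rank, t in enumerate(block):
            w[t] += 1.0 + tilt * np.cos(2 * np.pi * rank / len(block) - phase)
        comp = w / w.sum()
        mod = module_names[m] if m < len(module_names) else f"module{m}"
        preset = _DEFAULT_AREAS.get(mod, ())
        name = preset[j_in] if j_in < len(preset) else f"{mod}-{j_in}"
        areas.append(AreaSpec(name=name, module=mod,
                              composition=tuple(comp), width_um=width_um))
    return areas


def build_panel(config: SimulationConfig) -> PanelSpec:
    """Gene panel for a config: H1 markers first, then named filler genes."""
    names = ["Slc17a7", "Gad1"]
    names += list(_PANEL_GENES[:min(len(_PANEL_GENES), config.n_genes - 2)])
    names += [f"Gene{i:03d}" for i in range(len(names), config.n_genes)]
    return PanelSpec(genes=tuple(names[:config.n_genes]))


def build_type_means(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic mean-expression matrix (types x genes).

    Rows are excitatory H3 types followed by inhibitory types.  Marker
    structure: the two H1 markers, 4 subclass (H2) markers per H2 type, 2
    cluster (H3) markers per H3 type, 2 markers per inhibitory type, a few
    housekeeping genes, and low background elsewhere.  Mean totals land
    near 80-90 reads per cell at the default panel size.
    """
    panel = build_panel(config)
    g = config.n_genes
    n_h3, n_inh = config.n_h3, config.n_inhibitory
    types = config.h3_names + config.inhibitory_names
    m = np.full((len(types), g), 0.2)

    slc, gad = panel.index_of("Slc17a7"), panel.index_of("Gad1")
    m[:n_h3, slc] = 12.0
    m[:n_h3, gad] = 0.05
    m[n_h3:, gad] = 12.0
    m[n_h3:, slc] = 0.05

    cursor = 2

    def take(k: int) -> list[int]:
        nonlocal cursor
        idx = [i % g for i in range(cursor, cursor + k)]
        cursor += k
        return idx

    per_h2 = max(1, min(4, (g - 2) // (3 * config.n_h2)))
    for h2 in range(config.n_h2):
        rows = slice(h2 * config.h3_per_h2, (h2 + 1) * config.h3_per_h2)
        for gi in take(per_h2):
            m[rows, gi] = 8.0
            m[np.r_[0:n_h3][np.r_[0:n_h3] // config.h3_per_h2 != h2], gi] = 0.3
    for h3 in range(n_h3):
        for gi in take(2):
            m[h3, gi] = 6.0
    for inh in range(n_inh):
        for gi in take(2):
            m[n_h3 + inh, gi] = 8.0
    for gi in take(min(4, max(0, g - cursor))):
        m[:, gi] = 2.0
    return pd.DataFrame(m, index=types, columns=list(panel.genes))


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, n: int,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws, n cells x len(mu) genes."""
    if dispersion <= 0:
        return rng.poisson(np.broadcast_to(mu, (n, mu.size)))
    r = 1.0 / dispersion
    lam = rng.gamma(r, np.broadcast_to(mu / r, (n, mu.size)))
    return rng.poisson(lam)


def _shifted_composition(config: SimulationConfig, area: AreaSpec,
                         condition: str) -> np.ndarray:
    comp = np.asarray(area.composition, dtype=float)
    perturbed = condition == config.conditions[1]
    if (perturbed and config.shift_weight > 0
            and area.name == config.shift_source):
        by_name = {a.name: np.asarray(a.composition) for a in config.areas}
        target = np.mean([by_name[t] for t in config.shift_targets], axis=0)
        lam = config.shift_weight
        comp = (1 - lam) * comp + lam * target
    return comp


def simulate(config: SimulationConfig) -> tuple[CellTable, GroundTruth]:
    """Generate a full synthetic study; deterministic given ``config.seed``.

    Raises ``ValueError`` if any area would receive zero cells per slice.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = build_panel(config)
    means = build_type_means(config).to_numpy()
    n_h3, n_inh = config.n_h3, config.n_inhibitory
    type_names = config.h3_names + config.inhibitory_names
    h2_of_h3 = [config.h2_names[t // config.h3_per_h2] for t in range(n_h3)]
    depth_mean = np.asarray(config.depth_means, dtype=float)

    for a in config.areas:
        if int(round(a.width_um * config.cells_per_um)) < 1:
            raise ValueError(f"area {a.name} would receive zero cells")

    # per-litter multiplicative gene factors (log-normal)
    litter_ids = [f"litter{l}" for l in range(config.n_litters)]
    litter_factor = np.exp(rng.normal(
        0.0, config.litter_effect_sd, size=(config.n_litters, config.n_genes)))

    # area mediolateral spans (shared across slices)
    starts = np.concatenate([[0.0], np.cumsum(
        [a.width_um for a in config.areas])])[:-1]

    blocks: list[pd.DataFrame] = []
    type_blocks: list[np.ndarray] = []
    area_composition: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        for a in config.areas:
            area_composition[(cond, a.name)] = _shifted_composition(
                config, a, cond)

    for l in range(config.n_litters):
        for cond, tag in zip(config.conditions, ("C", "E")):
            brain = f"L{l}{tag}"
            for a, x0 in zip(config.areas, starts):
                base = area_composition[(cond, a.name)]
                if np.isfinite(config.dirichlet_conc):
                    comp = np.zeros_like(base)
                    pos = base > 0
                    comp[pos] = rng.dirichlet(
                        config.dirichlet_conc * base[pos])
                else:
                    comp = base
                n_per_slice = int(round(a.width_um * config.cells_per_um))
                for s in range(config.n_slices):
                    n = n_per_slice
                    is_inh = rng.random(n) < config.inhibitory_fraction
                    t = np.empty(n, dtype=int)
                    n_e = int((~is_inh).sum())
                    t[~is_inh] = rng.choice(n_h3, size=n_e, p=comp)
                    t[is_inh] = n_h3 + rng.integers(0, n_inh,
                                                    size=int(is_inh.sum()))
                    x = x0 + rng.uniform(0, a.width_um, size=n)
                    depth = np.where(
                        is_inh, rng.uniform(0, 1, size=n),
                        np.clip(rng.normal(
                            depth_mean[np.minimum(t, n_h3 - 1)
                                       // config.h3_per_h2],
                            config.depth_sd, size=n), 0, 1))
                    blocks.append(pd.DataFrame({
                        "brain": brain, "litter": litter_ids[l],
                        "condition": cond, "slice": s,
                        "x_um": x, "depth": depth, "area": a.name}))
                    type_blocks.append(t)

    obs = pd.concat(blocks, ignore_index=True)
    obs.insert(0, "cell_id", [f"c{i:07d}" for i in range(len(obs))])
    t_arr = np.concatenate(type_blocks)

    # counts, grouped by (litter, type) for vectorized NB sampling
    counts = np.zeros((len(obs), config.n_genes), dtype=np.int32)
    lit_codes = obs["litter"].map({lid: i for i, lid in
                                   enumerate(litter_ids)}).to_numpy()
    for l in range(config.n_litters):
        for t in range(n_h3 + n_inh):
            sel = np.flatnonzero((lit_codes == l) & (t_arr == t))
            if sel.size == 0:
                continue
            mu = means[t] * litter_factor[l]
            counts[sel] = _nb_counts(rng, mu, sel.size, config.nb_dispersion)

    h2_lookup = np.asarray(h2_of_h3 + config.inhibitory_names, dtype=object)
    labels = pd.DataFrame({
        "true_h1": np.where(t_arr < n_h3, "excitatory", "inhibitory"),
        "true_h2": h2_lookup[t_arr],
        "true_h3": np.asarray(type_names, dtype=object)[t_arr],
        "is_doublet": False,
    }, index=obs["cell_id"].to_numpy())
    labels.index.name = "cell_id"

    cells = CellTable(obs, sp.csr_matrix(counts), list(panel.genes))
    truth = GroundTruth(
        labels=labels, area_composition=area_composition,
        modules=config.modules, h3_names=config.h3_names,
        h2_names=config.h2_names,
        inhibitory_names=config.inhibitory_names,
        shift_source=config.shift_source,
        shift_targets=tuple(config.shift_targets or ()) or None,
        shift_weight=config.shift_weight)

    if config.doublet_rate > 0:
        cells, flags = inject_doublets(
            cells, config.doublet_rate,
            seed=int(rng.integers(0, 2 ** 31)),
            thickness_um=config.cortex_thickness_um)
        truth.labels = truth.labels.loc[cells.obs["cell_id"]]
        truth.labels["is_doublet"] = flags.reindex(
            truth.labels.index, fill_value=False).to_numpy()
    return cells, truth


def inject_doublets(cells: CellTable, d: float, seed: int = 0,
                    thickness_um: float = 1000.0,
                    ) -> tuple[CellTable, pd.Series]:
    """Merge a fraction ``d`` of cells with their nearest spatial neighbour.

    Each selected host cell absorbs the counts of its nearest remaining
    neighbour on the same slice of the same brain (distance on
    mediolateral position and physical depth); the neighbour is removed.
    Returns the new table and a boolean flag series over surviving cells.
    """
    from scipy.spatial import cKDTree

    if not (0 <= d < 1):
        raise ValueError("doublet rate must lie in [0, 1)")
    n = cells.n_cells
    flags = pd.Series(False, index=cells.obs["cell_id"].to_numpy())
    if d == 0 or n == 0:
        return cells.copy(), flags

    rng = np.random.default_rng(seed)
    host_mask = rng.random(n) < d
    removed = np.zeros(n, dtype=bool)
    merge_pairs: list[tuple[int, int]] = []
    xy = np.column_stack([cells.obs["x_um"].to_numpy(),
                          cells.obs["depth"].to_numpy() * thickness_um])
    for _, grp in cells.obs.groupby(["brain", "slice"], sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        tree = cKDTree(xy[idx])
        hosts = idx[host_mask[idx]]
        k = min(6, idx.size)
        for h in hosts:
            if removed[h]:
                continue
            _, nbrs = tree.query(xy[h], k=k)
            for j in np.atleast_1d(nbrs):
                cand = idx[j]
                if cand == h or removed[cand] or host_mask[cand]:
                    continue
                merge_pairs.append((h, cand))
                removed[cand] = True
                break

    # merged counts = (I + sum_{(h,b)} e_h e_b^T) @ counts, then drop absorbed
    if merge_pairs:
        hs, bs = zip(*merge_pairs)
        merge = sp.coo_matrix(
            (np.ones(len(hs)), (np.asarray(hs), np.asarray(bs))),
            shape=(n, n))
        counts = (sp.identity(n, format="csr") + merge.tocsr()) @ cells.counts
    else:
        counts = cells.counts.copy()
    keep = ~removed
    out = CellTable(cells.obs.loc[keep], sp.csr_matrix(counts)[keep],
                    cells.genes)
    host_ids = set(cells.obs["cell_id"].iloc[[h for h, _ in merge_pairs]])
    flags = pd.Series(out.obs["cell_id"].isin(host_ids).to_numpy(),
                      index=out.obs["cell_id"].to_numpy())
    return out, flags


def simulate_reference(config: SimulationConfig, clusters_per_h3: int = 1,
                       offset: float = 0.3,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference taxonomy of cluster-mean profiles on the same gene panel.

    With ``clusters_per_h3 == 1`` the reference clusters equal the
    excitatory H3 generative means (a bijective correspondence).  With 2,
    each H3 type is split into two reference clusters whose means are
    tilted up/down by ``offset`` on alternating genes, yielding a recorded
    one-to-many correspondence.
    """
    if clusters_per_h3 not in (1, 2):
        raise ValueError("clusters_per_h3 must be 1 or 2")
    means = build_type_means(config).iloc[:config.n_h3]
    profiles, mapping = [], []
    for h3, mu in means.iterrows():
        if clusters_per_h3 == 1:
            profiles.append(pd.Series(mu, name=f"ref|{h3}"))
            mapping.append({"reference": f"ref|{h3}", "h3": h3})
        else:
            tilt = np.where(np.arange(mu.size) % 2 == 0, 1 + offset,
                            1 - offset)
            profiles.append(pd.Series(mu.to_numpy() * tilt, index=mu.index,
                                      name=f"ref|{h3}|a"))
            profiles.append(pd.Series(mu.to_numpy() / tilt, index=mu.index,
                                      name=f"ref|{h3}|b"))
            mapping.append({"reference": f"ref|{h3}|a", "h3": h3})
            mapping.append({"reference": f"ref|{h3}|b", "h3": h3})
    return pd.DataFrame(profiles), pd.DataFrame(mapping)
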
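"""Synthetic community generator with full ground truth.

Produces trees, regime paintings, traits evolved under BM/OU/EB, gap- vs
shade-archetype irradiance spectra, fisheye images with known sky fraction,
elliptical wing silhouettes with known area and aspect ratio, and
individual-level record tables — everything the pipeline estimates has a
recorded true value, and every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import visual_model as vm
from .axes import MIMETIC_CLUSTERS, RING_TO_CLUSTER
from .canopy import FisheyeImage, MAX_ZENITH_DEG, RIM_ZENITH_DEG
from .evo_models import RegimeMap
from .trees import Phylogeny


class SyntheticError(RuntimeError):
    pass


# seed offsets so one master seed spawns independent per-stage streams
SEED_OFFSETS = {
    "tree": 11,
    "regimes": 23,
    "trait": 37,
    "individuals": 51,
    "spectra": 67,
    "images": 83,
}


# -- tree ------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rescale: bool = True,
) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on n tips, rescaled to unit depth
    unless ``rescale`` is off (raw time units expose the Yule expectations)."""
    if n_tips < 2:
        raise SyntheticError("need at least two tips")
    rng = np.random.default_rng(seed)
    # node bookkeeping: parent, birth time; root splits at t=0
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        v = active.pop(k)
        for _ in range(2):
            parent.append(v)
            btime.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    n_nodes = len(parent)
    is_tip = np.ones(n_nodes, dtype=bool)
    for p in parent:
        if p >= 0:
            is_tip[p] = False
    edge, labels = [], []
    tip_no = 0
    for v in range(n_nodes):
        if parent[v] < 0:
            edge.append(0.0)
        else:
            end = t_end if is_tip[v] else btime[_first_child_time(parent, btime, v)]
            edge.append(end - btime[v])
        if is_tip[v]:
            tip_no += 1
            labels.append(f"sp{tip_no:02d}")
        else:
            labels.append(None)
    tree = Phylogeny(parent, edge, labels)
    return tree.rescale(1.0) if rescale else tree


def _first_child_time(parent, btime, v) -> int:
    for u in range(len(parent)):
        if parent[u] == v:
            return u
    raise SyntheticError("internal node without children")


# -- regimes ---------------------------------------------------------------


def paint_regimes(
    tree: Phylogeny,
    mode: str = "tip-clustered",
    regimes: tuple[str, ...] = MIMETIC_CLUSTERS,
    q: float | None = None,
    seed: int | None = None,
) -> RegimeMap:
    """Regime painting of a tree.

    ``mk`` forward-simulates a single equal-rates history at rate ``q``.
    ``tip-clustered`` rejection-samples forward histories until every regime
    is present at the tips and polyphyletic (>= 2 independent origins), i.e.
    a history conditional on a mimicry-like tip clustering.
    """
    rng = np.random.default_rng(seed)
    if q is None:
        # aim for a handful of regime shifts across the whole tree
        q = 5.0 / float(tree.edge_len.sum())
    if mode == "mk":
        return _forward_mk(tree, regimes, q, rng)
    if mode != "tip-clustered":
        raise SyntheticError(f"unknown painting mode {mode!r}")
    for _ in range(100):
        rmap = _forward_mk(tree, regimes, q, rng)
        if _all_polyphyletic(tree, rmap.tip_regimes(), regimes):
            return rmap
    raise SyntheticError("could not draw a polyphyletic tip clustering in 100 tries")


def _all_polyphyletic(tree: Phylogeny, tip_states: dict[str, str], regimes) -> bool:
    counts = {r: 0 for r in regimes}
    for s in tip_states.values():
        counts[s] += 1
    if any(c == 0 for c in counts.values()):
        return False
    # a regime is polyphyletic here if its tips are not the leafset of one clade
    clades = {}
    for v in tree.postorder():
        if not tree.children[v]:
            clades[v] = {tree.labels[v]}
        else:
            clades[v] = set().union(*(clades[c] for c in tree.children[v]))
    clade_sets = set(frozenset(s) for s in clades.values())
    for r in regimes:
        tips_r = frozenset(lb for lb, s in tip_states.items() if s == r)
        if len(tips_r) >= 2 and tips_r in clade_sets:
            return False
    return True


def _forward_mk(tree, regimes, q, rng) -> RegimeMap:
    k = len(regimes)
    rate = (k - 1) * q
    root_reg = int(rng.integers(k))
    state_at: dict[int, int] = {tree.root: root_reg}
    hist: dict[int, list[tuple[float, str]]] = {}
    for v in tree.preorder():
        for c in tree.children[v]:
            t = float(tree.edge_len[c])
            state = state_at[v]
            segs, pos = [], 0.0
            while True:
                wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if pos + wait >= t:
                    segs.append((t - pos, regimes[state]))
                    break
                segs.append((wait, regimes[state]))
                others = [s for s in range(k) if s != state]
                state = int(rng.choice(others))
                pos += wait
            segs = [(max(d, 1e-300), r) for d, r in segs if d > 0] or [(max(t, 1e-300), regimes[state])]
            hist[c] = segs
            state_at[c] = state
    return RegimeMap(tree, hist, regimes[root_reg], tuple(regimes))


# -- traits ----------------------------------------------------------------


def simulate_trait(
    rmap: RegimeMap,
    model: str = "OUM",
    sigma2: float | dict[str, float] = 1.0,
    alpha: float = 0.0,
    theta: dict[str, float] | None = None,
    r: float = 0.0,
    root_state: float | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Recursive trait simulation along the painted branches.

    BM: Normal(0, sigma2 dt) increments (regime-specific under BMM); OU:
    exact transition toward the segment regime's optimum; EB: time-rescaled
    BM with rate sigma2 * e^(r t).
    """
    model = model.upper()
    tree = rmap.tree
    rng = np.random.default_rng(seed)
    times = tree.node_times()
    if theta is None:
        theta = {reg: 0.0 for reg in rmap.regimes}
    if root_state is None:
        root_state = theta[rmap.root_regime] if model in ("OU1", "OUM") else 0.0
    value = {tree.root: float(root_state)}
    for v in tree.preorder():
        for c in tree.children[v]:
            y = value[v]
            t0 = times[v]
            for d, reg in rmap.histories[c]:
                s2 = sigma2[reg] if isinstance(sigma2, dict) else sigma2
                if model in ("BM1", "BMM"):
                    y += rng.normal(0.0, np.sqrt(s2 * d)) if s2 > 0 else 0.0
                elif model in ("OU1", "OUM"):
                    if alpha <= 0:
                        y += rng.normal(0.0, np.sqrt(s2 * d)) if s2 > 0 else 0.0
                    else:
                        th = theta[reg]
                        var = s2 * (-np.expm1(-2.0 * alpha * d)) / (2.0 * alpha)
                        y = th + (y - th) * np.exp(-alpha * d) + (
                            rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
                        )
                elif model == "EB":
                    if abs(r) < 1e-12:
                        var = s2 * d
                    else:
                        var = s2 * (np.exp(r * (t0 + d)) - np.exp(r * t0)) / r
                    y += rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
                else:
                    raise SyntheticError(f"unknown trait model {model!r}")
                t0 += d
            value[c] = y
    return pd.Series({tree.labels[tip]: value[tip] for tip in tree.tips})


# -- spectra ---------------------------------------------------------------

SPECTRAL_GRID = np.arange(310.0, 671.0, 1.0)


def archetype_spectrum(kind: str) -> vm.Spectrum:
    """Idealized forest irradiance archetypes (energy units).

    ``gap``: bright, broad, long-wavelength rich; ``shade``: dim and
    green-peaked, as under a closed canopy.
    """
    wl = SPECTRAL_GRID
    if kind == "gap":
        vals = 0.8 * np.exp(-(((wl - 560.0) / 260.0) ** 2)) + 0.15
    elif kind == "shade":
        vals = 0.015 * np.exp(-(((wl - 550.0) / 55.0) ** 2)) + 0.0008
    else:
        raise SyntheticError(f"unknown archetype {kind!r}")
    return vm.Spectrum(wl, vals, units="energy")


def mixed_spectrum(gap_weight: float) -> vm.Spectrum:
    g = archetype_spectrum("gap")
    s = archetype_spectrum("shade")
    w = float(np.clip(gap_weight, 0.0, 1.0))
    return vm.Spectrum(SPECTRAL_GRID, w * g.values + (1 - w) * s.values, units="energy")


def simulate_spectra(
    cluster_or_weight,
    n: int = 1,
    seed: int | None = None,
    intensity_sd_log: float = 0.2,
    shape_sd: float = 0.03,
) -> list[vm.Spectrum]:
    """Noisy spectra around an archetype (or a gap/shade mixture weight)."""
    rng = np.random.default_rng(seed)
    if isinstance(cluster_or_weight, str):
        weight = {"tiger-stripe": 0.8, "clearwing": 0.05, "confusa": 0.15}.get(
            cluster_or_weight
        )
        if weight is None:
            base = archetype_spectrum(cluster_or_weight)  # "gap" / "shade"
        else:
            base = mixed_spectrum(weight)
    else:
        base = mixed_spectrum(float(cluster_or_weight))
    out = []
    for _ in range(n):
        gain = np.exp(rng.normal(0.0, intensity_sd_log)) if intensity_sd_log > 0 else 1.0
        if shape_sd > 0:
            bumps = ndimage.gaussian_filter1d(rng.normal(0.0, 1.0, base.values.size), 30.0)
            shape = 1.0 + shape_sd * bumps / max(np.std(bumps), 1e-12)
        else:
            shape = 1.0
        vals = np.clip(base.values * gain * shape, 0.0, None)
        out.append(vm.Spectrum(base.wavelengths_nm, vals, units="energy"))
    return out


# -- images ----------------------------------------------------------------


def simulate_fisheye(
    gap_fraction_target: float,
    size_px: int = 240,
    seed: int | None = None,
    correlation_px: float = 3.0,
) -> tuple[FisheyeImage, float]:
    """Fisheye disc with sky placed by a thresholded correlated random field.

    The threshold is the field quantile that hits the target sky fraction
    within the 0-70 degree analysis cap; the realized fraction is returned as
    ground truth.
    """
    if not 0.0 <= gap_fraction_target <= 1.0:
        raise SyntheticError("target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.normal(size=(size_px, size_px)), correlation_px)
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    rr = np.hypot(yy - c, xx - c)
    radius = size_px / 2.0
    cap = rr <= radius * MAX_ZENITH_DEG / RIM_ZENITH_DEG
    disc = rr <= radius
    if gap_fraction_target >= 1.0:
        sky = disc.copy()
    elif gap_fraction_target <= 0.0:
        sky = np.zeros_like(disc)
    else:
        thr = np.quantile(field_[cap], 1.0 - gap_fraction_target)
        sky = field_ > thr
    rgb = np.zeros((size_px, size_px, 3), dtype=np.uint8)
    rgb[..., 0] = np.where(sky, 120, 20)
    rgb[..., 1] = np.where(sky, 160, 60)
    rgb[..., 2] = np.where(sky, 235, 25)
    rgb[~disc] = 0
    truth = float(sky[cap].mean())
    img = FisheyeImage(rgb, circle_center=(c, c), circle_radius_px=radius)
    return img, truth


def simulate_wing(
    area_mm2: float,
    aspect_ratio: float,
    scale_mm_per_px: float = 0.1,
    angle_deg: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Filled rotated ellipse silhouette with the requested area and axis ratio."""
    if aspect_ratio < 1.0:
        raise SyntheticError("aspect ratio must be >= 1")
    b_px = np.sqrt(area_mm2 / (np.pi * aspect_ratio)) / scale_mm_per_px
    a_px = aspect_ratio * b_px
    half = int(np.ceil(a_px)) + 4
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size] - half
    phi = np.radians(angle_deg)
    u = xx * np.cos(phi) + yy * np.sin(phi)
    w = -xx * np.sin(phi) + yy * np.cos(phi)
    mask = (u / a_px) ** 2 + (w / b_px) ** 2 <= 1.0
    img = np.where(mask, 255, 0).astype(np.uint8)
    truth = {
        "area_mm2": float(area_mm2),
        "aspect_ratio": float(aspect_ratio),
        "scale_mm_per_px": float(scale_mm_per_px),
        "angle_deg": float(angle_deg),
    }
    return img, truth


# -- community -------------------------------------------------------------


@dataclass
class SyntheticConfig:
    n_species: int = 45
    n_individuals: int = 785
    birth_rate: float = 1.0
    trait_model: str = "OUM"
    alpha: float = 6.93  # half-life = ln2/alpha = 10% of unit depth
    sigma2: float = 1.0
    # cluster optima on the latent light axis, separated by ~3 stationary sd
    theta: dict = field(default_factory=lambda: {
        "clearwing": -1.0, "confusa": 0.0, "tiger-stripe": 1.0,
    })
    species_effect_sd: float = 0.05
    individual_noise_sd: float = 0.15
    spectral_intensity_sd_log: float = 0.2
    spectral_shape_sd: float = 0.03
    flight_noise_sd: float = 0.3
    openness_noise_sd: float = 2.0
    wing_noise_sd: float = 1.0  # scales the per-trait wing noise
    geometric_p: float = 0.08  # individuals-per-species skew
    max_per_species: int = 65
    seed: int = 0


@dataclass
class SyntheticCommunity:
    config: SyntheticConfig
    tree: Phylogeny
    regime_map: RegimeMap
    species_table: pd.DataFrame
    records: pd.DataFrame
    latent: pd.Series  # true species values on the light axis

    def write(self, out_dir: str | Path, assets: bool = False) -> None:
        """Write the fixture tree: tables + Newick, optionally example assets
        (per-species spectra, fisheye and wing images with recorded truth)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.species_table.to_csv(out / "species.csv")
        self.records.to_csv(out / "records.csv", index=False)
        self.latent.rename("latent_light").to_csv(out / "truth.csv")
        prov = {"seed": self.config.seed, "n_species": self.config.n_species,
                "n_individuals": self.config.n_individuals,
                "trait_model": self.config.trait_model,
                "theta": self.config.theta}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        if assets:
            self._write_assets(out)

    def _write_assets(self, out: Path) -> None:
        from PIL import Image

        seed = self.config.seed * 1000 + SEED_OFFSETS["images"]
        spec_dir = out / "spectra"
        spec_dir.mkdir(exist_ok=True)
        stat_sd = np.sqrt(self.config.sigma2 / (2 * self.config.alpha)) \
            if self.config.alpha > 0 else 1.0
        for sp in self.tree.tip_labels:
            gw = 1.0 / (1.0 + np.exp(-self.latent[sp] / max(stat_sd, 1e-9)))
            spec = mixed_spectrum(float(gw))
            lines = [f"# species {sp}  gap_weight {gw:.6f}"]
            lines += [f"{w:.1f} {v:.8e}" for w, v in zip(spec.wavelengths_nm, spec.values)]
            (spec_dir / f"{sp}.txt").write_text("\n".join(lines) + "\n")
        img_dir = out / "fisheye"
        img_dir.mkdir(exist_ok=True)
        truths = {}
        for i, target in enumerate((0.2, 0.5, 0.8)):
            img, truth = simulate_fisheye(target, seed=seed + i)
            Image.fromarray(img.data).save(img_dir / f"fisheye_{i}.png")
            truths[f"fisheye_{i}.png"] = truth
        wing_dir = out / "wings"
        wing_dir.mkdir(exist_ok=True)
        meta = []
        for i, (area, ar) in enumerate(((200.0, 1.8), (250.0, 2.2), (300.0, 2.0))):
            img, truth = simulate_wing(area, ar, angle_deg=20.0 * i, seed=seed + 10 + i)
            Image.fromarray(img).save(wing_dir / f"wing_{i}.png")
            meta.append({"specimen": f"w{i}", "image": f"wing_{i}.png",
                         "mass_g": 0.05, "scale_mm_per_px": 0.1, "damaged": 0,
                         **{f"true_{k}": v for k, v in truth.items()}})
        pd.DataFrame(meta).to_csv(wing_dir / "meta.csv", index=False)
        (img_dir / "truth.json").write_text(json.dumps(truths, indent=2))


def _ring_for(cluster: str, rng: np.random.Generator) -> str:
    rings = [r for r, c in RING_TO_CLUSTER.items() if c == cluster]
    return str(rng.choice(rings))


def _sample_sizes(n_species: int, total: int, p: float, cap: int,
                  rng: np.random.Generator) -> np.ndarray:
    n = 1 + rng.geometric(p, size=n_species)
    n = np.minimum(n, cap)
    # adjust to the exact configured total, keeping every species >= 1
    diff = total - int(n.sum())
    while diff != 0:
        i = int(rng.integers(n_species))
        if diff > 0 and n[i] < cap:
            n[i] += 1
            diff -= 1
        elif diff < 0 and n[i] > 1:
            n[i] -= 1
            diff += 1
    return n


def simulate_community(config: SyntheticConfig | None = None) -> SyntheticCommunity:
    """Full ground-truth community bundle (no image/spectrum files in memory).

    The latent light-axis value evolves under the configured model with
    cluster-specific optima; it drives canopy openness, flight height and the
    gap/shade spectral mixture, so the downstream EC1 axis is a monotone
    readout of the latent truth. Wing traits follow an independent BM latent
    and therefore load on a second axis.
    """
    cfg = config or SyntheticConfig()
    seeds = {k: cfg.seed * 1000 + off for k, off in SEED_OFFSETS.items()}
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=seeds["tree"])
    rmap = paint_regimes(tree, mode="tip-clustered", seed=seeds["regimes"])
    latent = simulate_trait(
        rmap, model=cfg.trait_model, sigma2=cfg.sigma2, alpha=cfg.alpha,
        theta=cfg.theta, seed=seeds["trait"],
    )
    tip_cluster = rmap.tip_regimes()
    rng = np.random.default_rng(seeds["individuals"])
    ring = {sp: _ring_for(tip_cluster[sp], rng) for sp in tree.tip_labels}
    # species-level phylogenetic intercepts so the mixed model's assumed
    # structure is literally present in the data
    C = tree.mrca_times() / tree.depth
    u = rng.multivariate_normal(np.zeros(tree.n_tips), cfg.species_effect_sd**2 * C)
    species_effect = pd.Series(u, index=tree.tip_labels)
    wing_map = RegimeMap(tree, rmap.histories, rmap.root_regime, rmap.regimes)
    wing_latent = simulate_trait(wing_map, model="BM1", sigma2=0.5,
                                 seed=seeds["trait"] + 1)
    sizes = _sample_sizes(cfg.n_species, cfg.n_individuals, cfg.geometric_p,
                          cfg.max_per_species, rng)
    spec_rng = np.random.default_rng(seeds["spectra"])
    rows = []
    stationary_sd = np.sqrt(cfg.sigma2 / (2 * cfg.alpha)) if cfg.alpha > 0 else 1.0
    for sp, n_ind in zip(tree.tip_labels, sizes):
        z = (latent[sp] + species_effect[sp])
        gap_w = 1.0 / (1.0 + np.exp(-z / max(stationary_sd, 1e-9)))
        wlat = wing_latent[sp]
        for i in range(n_ind):
            zi = z + rng.normal(0.0, cfg.individual_noise_sd)
            gw_i = float(np.clip(1.0 / (1.0 + np.exp(-zi / max(stationary_sd, 1e-9))), 0.0, 1.0))
            spec = simulate_spectra(
                gw_i, n=1, seed=int(spec_rng.integers(2**31)),
                intensity_sd_log=cfg.spectral_intensity_sd_log,
                shape_sd=cfg.spectral_shape_sd,
            )[0]
            cs = vm.catch_set(spec)
            wsd = cfg.wing_noise_sd
            area = 220.0 + 25.0 * wlat + rng.normal(0.0, 8.0 * wsd) if wsd > 0 else 220.0 + 25.0 * wlat
            ar = 2.0 + 0.25 * wlat + (rng.normal(0.0, 0.05 * wsd) if wsd > 0 else 0.0)
            mass = max(0.040 + 0.006 * wlat + (rng.normal(0.0, 0.002 * wsd) if wsd > 0 else 0.0), 0.005)
            fh = 1.0 + 2.5 * gw_i + (rng.normal(0.0, cfg.flight_noise_sd) if cfg.flight_noise_sd > 0 else 0.0)
            op = 5.0 + 55.0 * gw_i + (rng.normal(0.0, cfg.openness_noise_sd) if cfg.openness_noise_sd > 0 else 0.0)
            rows.append({
                "species": sp,
                "mimicry_ring": ring[sp],
                "mimetic_cluster": tip_cluster[sp],
                "sex": "F" if rng.random() < 0.5 else "M",
                "flight_height_m": float(np.clip(fh, 0.1, None)),
                "canopy_openness_pct": float(np.clip(op, 0.0, 100.0)),
                "q_uv": cs.q_uv, "q_b": cs.q_b, "q_lw": cs.q_lw,
                "rel_uv": cs.rel_uv, "rel_b": cs.rel_b, "rel_lw": cs.rel_lw,
                "log10_photon_catch_lw": float(np.log10(cs.photon_catch_lw)),
                "wing_area_mm2": float(area),
                "wing_aspect_ratio": float(max(ar, 1.0)),
                "wing_loading_g_per_mm2": float(mass / area),
            })
    records = pd.DataFrame(rows)
    species_table = pd.DataFrame({
        "mimicry_ring": pd.Series(ring),
        "mimetic_cluster": pd.Series(tip_cluster),
        "true_optimum": pd.Series({sp: cfg.theta[tip_cluster[sp]] for sp in tree.tip_labels}),
        "latent_light": latent,
        "n_individuals": pd.Series(dict(zip(tree.tip_labels, sizes.astype(int)))),
    })
    species_table.index.name = "species"
    return SyntheticCommunity(cfg, tree, rmap, species_table, records, latent)
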
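"""Synthetic datasets with the statistical structure the analyses assume.

Every generator is seeded and bit-reproducible. The enrichment simulator
plants scored 30-bp rG4 regions on a small genome and gives high-stratum
regions a higher chance of receiving a soluble-interactome fragment,
emulating the preferential engagement of stable quadruplexes by soluble-
phase FUS; the curve simulators are the generative inverses of the binding
and melt fit models plus a logistic turbidity kinetic; the image simulators
plant disks with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingModel, binding_model
from .enrichment import G4Region, stratify_by_probability
from .io import GenomeTable, GenomicInterval, SequenceRecord
from .melt import MeltModel, melt_model
from .turbidity import TurbidityTrace

__all__ = [
    "EnrichmentSimParams",
    "MELT_FIXTURES",
    "simulate_enrichment_dataset",
    "simulate_titration",
    "simulate_melt",
    "simulate_turbidity",
    "simulate_droplet_image",
    "simulate_cell_image",
    "make_sequence_panel",
]

# Ground-truth melting temperatures (Celsius) used by the S1 melt fixtures:
# the rG4 of RNA S1 is more stable in K+ than in Na+.
MELT_FIXTURES: dict[str, dict[str, float]] = {
    "S1_K": {"t_m": 50.64, "delta_h": 180e3},
    "S1_Na": {"t_m": 36.98, "delta_h": 180e3},
}


@dataclass(frozen=True)
class EnrichmentSimParams:
    """Study conditions of the planted-enrichment dataset.

    30-bp rG4 regions scored with a Uniform(0,1) "G4 Probability" are placed
    on a 2 x 1 Mbp genome; each receives a 100-bp soluble-interactome
    fragment with probability p_soluble_high (high stratum) or p_soluble_low
    (low stratum; medium interpolates) and a droplet fragment with
    probability p_droplet. ``n_exclusive`` regions are forced to score 1.0,
    always receive a soluble fragment and never a droplet fragment — the
    planted soluble-exclusive ground truth.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 1_000_000, "chrS2": 1_000_000})
    n_g4: int = 300
    region_length: int = 30
    interactome_length: int = 100
    p_soluble_high: float = 0.8
    p_soluble_low: float = 0.3
    p_droplet: float = 0.3
    n_exclusive: int = 1

    def __post_init__(self) -> None:
        for p in (self.p_soluble_high, self.p_soluble_low, self.p_droplet):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_g4 < 3:
            raise ValueError("n_g4 must be >= 3")


def _place_nonoverlapping(n: int, length: int, genome: GenomeTable,
                          rng: np.random.Generator,
                          max_attempts: int = 10_000) -> list[tuple[str, int]]:
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    chroms = list(genome.entries)
    weights = np.array([genome.entries[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("genome too small to place regions without overlap")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, genome.entries[chrom] - length + 1))
        if any(start < e and s < start + length for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, start + length))
        out.append((chrom, start))
    return out


def simulate_enrichment_dataset(params: EnrichmentSimParams = EnrichmentSimParams(),
                                seed: int | None = None):
    """Generate (genome, stratified G4 regions, soluble set, droplet set,
    truth table) with planted high-stratum soluble enrichment."""
    rng = np.random.default_rng(seed)
    genome = GenomeTable(dict(params.chrom_lengths))
    placements = _place_nonoverlapping(params.n_g4, params.region_length,
                                       genome, rng)
    probs = rng.uniform(0.0, 1.0, size=params.n_g4)
    exclusive_ids = set(range(params.n_exclusive))
    for i in exclusive_ids:
        probs[i] = 1.0

    regions = [
        G4Region(GenomicInterval(chrom, start, start + params.region_length,
                                 name=f"g4_{i:04d}", score=float(probs[i])),
                 float(probs[i]))
        for i, (chrom, start) in enumerate(placements)
    ]
    regions = stratify_by_probability(regions)

    p_sol = {"low": params.p_soluble_low,
             "medium": 0.5 * (params.p_soluble_low + params.p_soluble_high),
             "high": params.p_soluble_high}
    soluble: list[GenomicInterval] = []
    droplet: list[GenomicInterval] = []
    truth_rows = []
    frag = params.interactome_length
    for region in regions:
        iv = region.interval
        is_exclusive = int(iv.name.split("_")[1]) in exclusive_ids
        get_sol = is_exclusive or rng.random() < p_sol[region.stratum]
        get_drop = (not is_exclusive) and rng.random() < params.p_droplet
        chrom_len = genome.entries[iv.chrom]
        for got, dest, tag in ((get_sol, soluble, "sol"),
                               (get_drop, droplet, "drop")):
            if not got:
                continue
            # fragment placed to overlap the region by >= 1 bp
            lo = max(0, iv.start - frag + 1)
            hi = min(chrom_len - frag, iv.end - 1)
            start = int(rng.integers(lo, hi + 1))
            dest.append(GenomicInterval(iv.chrom, start, start + frag,
                                        name=f"{tag}_{iv.name}"))
        truth_rows.append({
            "region": iv.name, "g4_probability": region.g4_probability,
            "stratum": region.stratum, "soluble_planted": bool(get_sol),
            "droplet_planted": bool(get_drop), "exclusive": bool(is_exclusive),
        })
    truth = pd.DataFrame(truth_rows)
    return genome, regions, soluble, droplet, truth


def simulate_titration(delta_a_max: float = 0.1, k_d: float = 50.0,
                       l_t: float = 8.0, a0: float = 0.05,
                       n_points: int = 12, x_min: float = 0.5,
                       x_max: float = 5_000.0, sigma: float = 0.002,
                       seed: int | None = None, series: str = "titration"
                       ) -> pd.DataFrame:
    """Noisy anisotropy titration from the ligand-depletion isotherm.

    Protein concentrations are log-spaced over [x_min, x_max] nM; Gaussian
    noise of s.d. ``sigma`` (anisotropy units) is added to each point.
    """
    rng = np.random.default_rng(seed)
    x = np.geomspace(x_min, x_max, n_points)
    y = binding_model(x, BindingModel(delta_a_max, k_d, l_t, a0))
    y = y + rng.normal(0.0, sigma, size=n_points)
    return pd.DataFrame({"series": series, "x": x, "y": y})


def simulate_melt(t_m: float = MELT_FIXTURES["S1_K"]["t_m"],
                  delta_h: float = 180e3,
                  m_folded: float = 0.0, b_folded: float = 6.0,
                  m_unfolded: float = 0.0, b_unfolded: float = 1.0,
                  t_start: float = 15.0, t_stop: float = 85.0,
                  pitch: float = 1.0, sigma: float = 0.1,
                  seed: int | None = None, series: str = "melt"
                  ) -> pd.DataFrame:
    """Noisy 265 nm melt curve from the two-state model.

    Defaults mirror the melt acquisition grid (15-85 C at 1 C pitch) with
    flat folded/unfolded baselines at 6 and 1 mdeg and Gaussian noise of
    s.d. ``sigma`` mdeg.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(t_start, t_stop + 0.5 * pitch, pitch)
    model = MeltModel(m_folded, b_folded, m_unfolded, b_unfolded, t_m, delta_h)
    y = melt_model(x, model) + rng.normal(0.0, sigma, size=len(x))
    return pd.DataFrame({"series": series, "x": x, "y": y})


def simulate_turbidity(plateau: float = 0.5, rate: float = 0.15,
                       t_half: float = 30.0, duration: float = 210.0,
                       rna_add_time: float | None = 90.0,
                       inhibitor_strength: float = 0.0,
                       enhancement: float = 1.0,
                       decay_rate: float = 0.1,
                       sigma: float = 0.005, seed: int | None = None,
                       rna_name: str = "", rna_concentration: float = 0.0,
                       role: str = "sample") -> TurbidityTrace:
    """Logistic turbidity trace with optional post-RNA reversal.

    The base kinetic is a logistic rise to ``plateau`` A395 (half time
    ``t_half`` min, rate /min) sampled in 1-min cycles. After
    ``rna_add_time`` the signal is multiplied by an exponential decay toward
    a floor of (1 - inhibitor_strength):

        m(dt) = (1 - s) + s * exp(-decay_rate * dt)

    so strength 0 leaves the trace flat and strength 1 decays to zero; the
    ``enhancement`` multiplier models the turbidity increase seen at low
    RNA concentrations (more, smaller droplets scatter more light).
    """
    if not (0.0 <= inhibitor_strength <= 1.0):
        raise ValueError("inhibitor_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5, 1.0)
    y = plateau / (1.0 + np.exp(-rate * (t - t_half)))
    if rna_add_time is not None:
        post = t >= rna_add_time
        dt = t[post] - rna_add_time
        s = inhibitor_strength
        y[post] = y[post] * enhancement * ((1.0 - s) + s * np.exp(-decay_rate * dt))
    y = y + rng.normal(0.0, sigma, size=len(t))
    return TurbidityTrace(t, y, rna_name=rna_name,
                          rna_concentration=rna_concentration,
                          rna_add_time=rna_add_time, role=role)


def _add_disk(grid: np.ndarray, cy: int, cx: int, radius: int,
              value: float) -> None:
    yy, xx = np.ogrid[:grid.shape[0], :grid.shape[1]]
    grid[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = value


def _place_disks(shape: tuple[int, int], n: int, radii: tuple[int, int],
                 rng: np.random.Generator, max_attempts: int = 1000,
                 margin: int = 2) -> list[tuple[int, int, int]]:
    disks: list[tuple[int, int, int]] = []
    attempts = 0
    while len(disks) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place requested disks without overlap")
        r = int(rng.integers(radii[0], radii[1] + 1))
        cy = int(rng.integers(r + margin, shape[0] - r - margin))
        cx = int(rng.integers(r + margin, shape[1] - r - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + margin) ** 2
               for y, x, rr in disks):
            disks.append((cy, cx, r))
    return disks


def simulate_droplet_image(shape: tuple[int, int] = (512, 512),
                           n_droplets: int = 7,
                           radius_range: tuple[int, int] = (4, 10),
                           inside: float = 200.0, background: float = 100.0,
                           sigma: float = 2.0, seed: int | None = None):
    """Flat background with planted non-overlapping bright disks.

    Returns (grid, truth_labels, disks) where ``disks`` is a list of
    (row, col, radius) and truth_labels numbers the planted disks 1..n.
    """
    if min(shape) < 16:
        raise ValueError("image must be at least 16x16")
    if radius_range[0] < 2:
        raise ValueError("radii must be >= 2 px")
    if inside <= 0 or background <= 0:
        raise ValueError("intensities must be positive")
    rng = np.random.default_rng(seed)
    grid = np.full(shape, background, dtype=float)
    labels = np.zeros(shape, dtype=int)
    disks = _place_disks(shape, n_droplets, radius_range, rng)
    for i, (cy, cx, r) in enumerate(disks, start=1):
        _add_disk(grid, cy, cx, r, inside)
        lab = np.zeros(shape)
        _add_disk(lab, cy, cx, r, i)
        labels[lab > 0] = i
    grid += rng.normal(0.0, sigma, size=shape)
    return grid, labels, disks


def simulate_cell_image(shape: tuple[int, int] = (256, 256),
                        n_nuclei: int = 2, nucleus_radius: int = 30,
                        n_foci: int = 12, foci_radius: int = 3,
                        shared_fraction: float = 1.0,
                        foci_intensity: float = 200.0,
                        nuclear_fraction: float = 0.25,
                        background: float = 10.0, sigma: float = 1.0,
                        seed: int | None = None) -> dict[str, np.ndarray]:
    """Two-channel foci image with a nuclei channel and known ground truth.

    A fraction ``shared_fraction`` of each channel's foci sit at positions
    common to both channels (colocalized); ``nuclear_fraction`` of foci are
    planted inside nuclei, the rest in the cytoplasm. Returns a dict with
    channels ``a``, ``b``, ``nuclei`` plus boolean truth masks
    ``truth_cyto_a``/``truth_cyto_b`` of the planted cytoplasmic foci.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nuclei_grid = np.full(shape, background, dtype=float)
    nuclei_mask = np.zeros(shape, dtype=bool)
    nuclei = _place_disks(shape, n_nuclei, (nucleus_radius, nucleus_radius),
                          rng, margin=6)
    for cy, cx, r in nuclei:
        _add_disk(nuclei_grid, cy, cx, r, 200.0)
        m = np.zeros(shape)
        _add_disk(m, cy, cx, r, 1.0)
        nuclei_mask |= m > 0

    n_nuclear = int(round(nuclear_fraction * n_foci))
    n_cyto = n_foci - n_nuclear
    n_shared = int(round(shared_fraction * n_cyto))

    def draw_positions(n: int, inside_nuclei: bool) -> list[tuple[int, int]]:
        pts: list[tuple[int, int]] = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 20_000:
                raise ValueError("could not place foci")
            cy = int(rng.integers(foci_radius + 1, shape[0] - foci_radius - 1))
            cx = int(rng.integers(foci_radius + 1, shape[1] - foci_radius - 1))
            if nuclei_mask[cy, cx] != inside_nuclei:
                continue
            if any(abs(cy - y) < 4 * foci_radius and abs(cx - x) < 4 * foci_radius
                   for y, x in pts):
                continue
            pts.append((cy, cx))
        return pts

    shared_pts = draw_positions(n_shared, inside_nuclei=False)
    own_a = draw_positions(n_cyto - n_shared, inside_nuclei=False)
    own_b = draw_positions(n_cyto - n_shared, inside_nuclei=False)
    nuclear_pts = draw_positions(n_nuclear, inside_nuclei=True) if n_nuclear else []

    def render(points: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
        grid = np.full(shape, background, dtype=float)
        mask = np.zeros(shape, dtype=bool)
        for cy, cx in points:
            _add_disk(grid, cy, cx, foci_radius, foci_intensity)
            m = np.zeros(shape)
            _add_disk(m, cy, cx, foci_radius, 1.0)
            mask |= m > 0
        return grid, mask

    grid_a, cyto_a = render(shared_pts + own_a)
    grid_b, cyto_b = render(shared_pts + own_b)
    for cy, cx in nuclear_pts:
        _add_disk(grid_a, cy, cx, foci_radius, foci_intensity)
        _add_disk(grid_b, cy, cx, foci_radius, foci_intensity)
    grid_a += rng.normal(0.0, sigma, size=shape)
    grid_b += rng.normal(0.0, sigma, size=shape)
    nuclei_grid += rng.normal(0.0, sigma, size=shape)
    return {"a": grid_a, "b": grid_b, "nuclei": nuclei_grid,
            "truth_cyto_a": cyto_a, "truth_cyto_b": cyto_b,
            "nuclei_mask": nuclei_mask}


def make_sequence_panel(seed: int | None = None) -> list[SequenceRecord]:
    """Deterministic panel of benchmark RNAs.

    Contains the quadruplex-positive members (GGU)8, the C9orf72 repeat
    (G4C2)4 and a TERRA-like (UUAGGG)4, plus a poly-A negative control and
    G-dispersed scrambles in which no two guanines are adjacent (quadruplex
    ablated). The fixed members never use the seed.
    """
    del seed  # fixed members are deterministic
    return [
        SequenceRecord("GGU8", "GGU" * 8),
        SequenceRecord("G4C2x4", "GGGGCC" * 4),
        SequenceRecord("TERRA4", "UUAGGG" * 4),
        SequenceRecord("polyA", "A" * 24),
        SequenceRecord("scramble_G4neg_1", "GAUGACUGAUACGAUCAGUAGACU"),
        SequenceRecord("scramble_G4neg_2", "AGUCAGUAGCAUGAUCAGUACGAU"),
    ]
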
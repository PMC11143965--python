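"""Synthetic study generator with known ground truth.

Emulates the coculture experiment that motivates the pipeline: 4 Schwann-cell
(SC) single cultures, 4 fibroblast (FB) single cultures and 16 SC-FB
cocultures (all pairings) whose SC fraction, measured by flow cytometry, falls
near 0.6-0.7. Counts are gamma-Poisson (negative binomial) with a mean-
dispersion trend alpha(mu) = a0/mu + a1, allocated multinomially at a fixed
per-sample library size so totals are conserved exactly.

A configurable subset of "interaction genes" is perturbed multiplicatively
*only in real cocultures*; everywhere else a real coculture's expected gene
proportions are the composition-weighted mixture of the two single-culture
profiles, which is exactly the null the downstream virtual-coculture test
assumes. The generator also produces matching read pools (gene of origin
encoded in the read name), secretome panels, and spheroid micrographs with
controllable fragmentation, so every pipeline stage can be scored against
truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, SecretomePanel, SpheroidImage
from .errors import ConfigError, GenerationError

__all__ = [
    "SimulationConfig",
    "simulate_single_profiles",
    "simulate_coculture_experiment",
    "simulate_read_pool",
    "simulate_secretome",
    "simulate_spheroid_image",
    "simulate_nuclei_field",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic coculture study.

    Defaults mirror the study design being emulated: 4 SC and 4 FB single
    cultures, cocultures formed from every SC x FB pairing (16), SC fractions
    drawn uniformly from [0.6, 0.7].

    ``interaction_fraction`` of genes receive a multiplicative perturbation of
    ``2**interaction_log2fc`` in real cocultures only (sign randomised per gene
    when ``signed_effects``); these are drawn from genes whose expected count
    at the reference depth is at least ``interaction_min_count``, since a gene
    silent in both cell types cannot carry an interaction signal.

    ``anchor`` selects what a real coculture's expected profile is a mixture
    of: ``"celltype"`` mixes the cell-type mean profiles (every sample is an
    independent replicate of its type — the regime in which the paired test's
    independence assumptions hold exactly), while ``"singles"`` mixes the
    *observed* single-culture count profiles, emulating a coculture assembled
    from the very cultures that were measured as singles, so the mixture null
    is exactly true given the singles.
    """

    n_genes: int = 10_000
    n_sc_cultures: int = 4
    n_fb_cultures: int = 4
    pairing: str = "all"  # "all" (cartesian) or "matched" (1:1)
    anchor: str = "celltype"  # what a real coculture's expectation mixes (see below)
    composition_range: tuple[float, float] = (0.6, 0.7)
    interaction_fraction: float = 0.02
    interaction_log2fc: float | tuple[float, float] = 1.0  # magnitude, or (lo, hi) range
    signed_effects: bool = True
    interaction_min_count: float = 20.0
    celltype_diff_fraction: float = 0.3
    celltype_log2fc: float = 2.0
    dispersion_a0: float = 2.0
    dispersion_a1: float = 0.02
    library_size_range: tuple[int, int] = (1_500_000, 2_500_000)
    # secretome block
    n_analytes: int = 20
    secretome_cv: float = 0.2
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_genes < 1 or self.n_sc_cultures < 1 or self.n_fb_cultures < 1:
            raise ConfigError("n_genes and culture counts must be positive")
        lo, hi = self.composition_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("composition_range must be an interval within [0, 1]")
        for name in ("interaction_fraction", "celltype_diff_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        llo, lhi = self.library_size_range
        if llo < 1 or lhi < llo:
            raise ConfigError("library_size_range must satisfy 1 <= lo <= hi")
        if self.pairing not in ("all", "matched"):
            raise ConfigError("pairing must be 'all' or 'matched'")
        if self.pairing == "matched" and self.n_sc_cultures != self.n_fb_cultures:
            raise ConfigError("matched pairing needs equal SC and FB culture counts")
        if self.anchor not in ("celltype", "singles"):
            raise ConfigError("anchor must be 'celltype' or 'singles'")
        if self.secretome_cv < 0 or self.n_analytes < 1:
            raise ConfigError("n_analytes must be >= 1 and secretome_cv >= 0")
        return self


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one root SeedSequence per config seed; fixed substream per generator
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _celltype_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Mean relative-abundance vectors for the two cell types.

    Gene abundances are lognormal (a wide, realistic expression distribution);
    a ``celltype_diff_fraction`` of genes differ between SC and FB by
    ``2**(+/- celltype_log2fc)`` so the two profiles are distinguishable.
    """
    base = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    q_sc = base.copy()
    q_fb = base.copy()
    n_diff = int(round(config.celltype_diff_fraction * config.n_genes))
    if n_diff:
        idx = rng.choice(config.n_genes, size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        q_fb[idx] *= 2.0 ** (signs * config.celltype_log2fc)
    return q_sc / q_sc.sum(), q_fb / q_fb.sum()


def _effect_magnitudes(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    fc = config.interaction_log2fc
    if isinstance(fc, (tuple, list)):
        lo, hi = fc
        return rng.uniform(float(lo), float(hi), size=n)
    return np.full(n, float(fc))


def _dispersion(config: SimulationConfig, mean_counts: np.ndarray) -> np.ndarray:
    mu = np.maximum(mean_counts, 1e-8)
    return config.dispersion_a0 / mu + config.dispersion_a1


def _nb_sample_column(
    rng: np.random.Generator,
    proportions: np.ndarray,
    library_size: int,
    alpha: np.ndarray,
) -> np.ndarray:
    """One gamma-Poisson sample at an exact total count.

    Gene rates are gamma-perturbed around ``proportions`` (shape 1/alpha),
    renormalised, then allocated multinomially at ``library_size``. Marginal
    per-gene variance approximates mu + alpha*mu^2; the column total is exact.
    """
    with np.errstate(divide="ignore"):
        shape = np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), np.inf)
    lam = np.where(
        np.isfinite(shape) & (proportions > 0),
        rng.gamma(np.where(np.isfinite(shape), shape, 1.0), 1.0) * proportions
        / np.where(np.isfinite(shape), shape, 1.0),
        proportions,
    )
    total = lam.sum()
    if total <= 0:
        raise GenerationError("degenerate profile: all proportions zero")
    return rng.multinomial(library_size, lam / total)


def _reference_depth(config: SimulationConfig) -> float:
    lo, hi = config.library_size_range
    return float(np.sqrt(float(lo) * float(hi)))


def simulate_single_profiles(config: SimulationConfig) -> ExpressionMatrix:
    """Simulate the SC and FB single-culture count columns."""
    config.validate()
    rng = _rng(config, 1)
    q_sc, q_fb = _celltype_profiles(config, rng)
    depth = _reference_depth(config)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.library_size_range

    columns, meta = {}, []
    for kind, n, q in (("SC", config.n_sc_cultures, q_sc), ("FB", config.n_fb_cultures, q_fb)):
        alpha = _dispersion(config, q * depth)
        for i in range(n):
            sid = f"{kind}{i + 1}"
            lib = int(rng.integers(lo, hi + 1))
            columns[sid] = _nb_sample_column(rng, q, lib, alpha)
            meta.append(
                {"sample_id": sid, "role": "sc_single" if kind == "SC" else "fb_single",
                 "pair_id": "", "sc_culture_id": sid if kind == "SC" else "",
                 "fb_culture_id": sid if kind == "FB" else ""}
            )
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"), dtype=np.int64)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(counts, samples).validate()


def _pairings(config: SimulationConfig) -> list[tuple[str, str]]:
    sc = [f"SC{i + 1}" for i in range(config.n_sc_cultures)]
    fb = [f"FB{j + 1}" for j in range(config.n_fb_cultures)]
    if config.pairing == "all":
        return list(itertools.product(sc, fb))
    return list(zip(sc, fb))


def simulate_coculture_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate singles plus real cocultures with injected interaction effects.

    Returns the combined matrix (singles + real cocultures), the composition
    table (one row per coculture with its drawn SC fraction) and the ground
    truth. Each real coculture's expected gene proportions are
    ``p*q_SC + (1-p)*q_FB`` except for interaction genes, whose expectation is
    multiplied by ``2**log2fc`` (then renormalised for multinomial allocation).
    """
    config.validate()
    singles = simulate_single_profiles(config)
    rng = _rng(config, 2)
    q_sc, q_fb = _celltype_profiles(config, _rng(config, 1))  # same stream as singles
    depth = _reference_depth(config)
    genes = list(singles.gene_ids)

    # interaction genes: expressed genes only
    expected_mix = 0.65 * q_sc + 0.35 * q_fb
    eligible = np.flatnonzero(expected_mix * depth >= config.interaction_min_count)
    n_int = int(round(config.interaction_fraction * config.n_genes))
    n_int = min(n_int, eligible.size)
    idx = rng.choice(eligible, size=n_int, replace=False) if n_int else np.array([], int)
    lfc = np.zeros(config.n_genes)
    if n_int:
        mags = _effect_magnitudes(config, rng, n_int)
        signs = rng.choice([-1.0, 1.0], size=n_int) if config.signed_effects else 1.0
        lfc[idx] = mags * signs

    lo, hi = config.library_size_range
    plo, phi = config.composition_range
    columns, meta, comp_rows = {}, [], []
    for sc_id, fb_id in _pairings(config):
        cid = f"{sc_id}-{fb_id}"
        p = float(rng.uniform(plo, phi))
        if config.anchor == "singles":
            sc_obs = singles.counts[sc_id].to_numpy(dtype=float)
            fb_obs = singles.counts[fb_id].to_numpy(dtype=float)
            mix = p * sc_obs / sc_obs.sum() + (1.0 - p) * fb_obs / fb_obs.sum()
        else:
            mix = p * q_sc + (1.0 - p) * q_fb
        mix = mix * 2.0 ** lfc
        mix = mix / mix.sum()
        alpha = _dispersion(config, mix * depth)
        lib = int(rng.integers(lo, hi + 1))
        columns[cid] = _nb_sample_column(rng, mix, lib, alpha)
        meta.append(
            {"sample_id": cid, "role": "real", "pair_id": cid,
             "sc_culture_id": sc_id, "fb_culture_id": fb_id}
        )
        comp_rows.append(
            {"coculture_id": cid, "sc_culture_id": sc_id, "fb_culture_id": fb_id,
             "sc_fraction": p}
        )

    real = ExpressionMatrix(
        pd.DataFrame(columns, index=singles.counts.index, dtype=np.int64),
        pd.DataFrame(meta).set_index("sample_id"),
    )
    matrix = singles.concat(real)
    compositions = pd.DataFrame(comp_rows)
    truth = GroundTruth(
        interaction_genes=[genes[i] for i in idx],
        log2fc=pd.Series(lfc, index=singles.gene_ids, name="true_log2fc"),
        compositions=compositions,
    )
    return matrix, compositions, truth


# ---------------------------------------------------------------------------
# read pools

_READ_SEQ = b"ACGTACGTACGTACGTACGT"
_READ_QUAL = b"I" * len(_READ_SEQ)


def simulate_read_pool(
    profile: pd.Series,
    n_reads: int,
    seed: int,
    path,
) -> dict[str, int]:
    """Write a FASTQ pool of ``n_reads`` reads drawn from a count profile.

    Per-gene read counts are multinomial with the profile's (normalised)
    proportions. The gene of origin is the read name, so downstream counting
    is exact name-based tallying; sequences are constant dummies (sequence-
    level realism is out of scope). Returns the per-gene read counts.
    """
    if n_reads <= 0:
        raise ConfigError("n_reads must be positive")
    values = np.asarray(profile, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ConfigError("profile must have positive total")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
    gene_counts = rng.multinomial(int(n_reads), values / total)
    with open(path, "wb") as fh:
        for gene, c in zip(profile.index, gene_counts):
            if c == 0:
                continue
            record = b"@" + str(gene).encode() + b"\n" + _READ_SEQ + b"\n+\n" + _READ_QUAL + b"\n"
            fh.write(record * int(c))
    return {str(g): int(c) for g, c in zip(profile.index, gene_counts) if c}


# ---------------------------------------------------------------------------
# secretome

def simulate_secretome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[SecretomePanel, GroundTruth]:
    """Simulate analyte concentrations for singles and real cocultures.

    Baseline single-culture concentrations are lognormal around cell-type
    means; a ``interaction_fraction`` of analytes is perturbed by
    ``2**interaction_log2fc`` in real cocultures on top of the composition-
    weighted mixture. Measurement noise is lognormal with CV
    ``secretome_cv``.
    """
    config.validate()
    cfg = config if seed is None else replace(config, seed=int(seed))
    rng = _rng(cfg, 4)
    analytes = [f"A{i:02d}" for i in range(cfg.n_analytes)]
    mean_sc = rng.lognormal(mean=4.0, sigma=1.0, size=cfg.n_analytes)  # ~pg/mL scale
    mean_fb = rng.lognormal(mean=4.0, sigma=1.0, size=cfg.n_analytes)

    n_int = int(round(cfg.interaction_fraction * cfg.n_analytes))
    idx = rng.choice(cfg.n_analytes, size=n_int, replace=False) if n_int else np.array([], int)
    lfc = np.zeros(cfg.n_analytes)
    if n_int:
        lfc[idx] = _effect_magnitudes(cfg, rng, n_int)

    sigma = np.sqrt(np.log1p(cfg.secretome_cv**2))

    def noisy(mean_vec):
        if sigma == 0:
            return mean_vec.copy()
        return mean_vec * rng.lognormal(-0.5 * sigma**2, sigma, size=mean_vec.shape)

    columns, meta, comp_rows = {}, [], []
    for i in range(cfg.n_sc_cultures):
        sid = f"SC{i + 1}"
        columns[sid] = noisy(mean_sc)
        meta.append({"sample_id": sid, "role": "sc_single", "pair_id": "",
                     "sc_culture_id": sid, "fb_culture_id": ""})
    for j in range(cfg.n_fb_cultures):
        sid = f"FB{j + 1}"
        columns[sid] = noisy(mean_fb)
        meta.append({"sample_id": sid, "role": "fb_single", "pair_id": "",
                     "sc_culture_id": "", "fb_culture_id": sid})
    plo, phi = cfg.composition_range
    for sc_id, fb_id in _pairings(cfg):
        cid = f"{sc_id}-{fb_id}"
        p = float(rng.uniform(plo, phi))
        if cfg.anchor == "singles":
            mix = p * columns[sc_id] + (1.0 - p) * columns[fb_id]
        else:
            mix = p * mean_sc + (1.0 - p) * mean_fb
        columns[cid] = noisy(mix * 2.0**lfc)
        meta.append({"sample_id": cid, "role": "real", "pair_id": cid,
                     "sc_culture_id": sc_id, "fb_culture_id": fb_id})
        comp_rows.append({"coculture_id": cid, "sc_culture_id": sc_id,
                          "fb_culture_id": fb_id, "sc_fraction": p})

    values = pd.DataFrame(columns, index=pd.Index(analytes, name="analyte"))
    panel = SecretomePanel(values, pd.DataFrame(meta).set_index("sample_id")).validate()
    truth = GroundTruth(
        interaction_genes=[analytes[i] for i in idx],
        log2fc=pd.Series(lfc, index=values.index, name="true_log2fc"),
        compositions=pd.DataFrame(comp_rows),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# images

def _disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_spheroid_image(
    main_radius_px: float,
    fragment_areas_px: list[float],
    live_dead_ratio: float,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    foreground: float = 1000.0,
    noise_sd: float = 5.0,
    max_tries: int = 200,
) -> tuple[SpheroidImage, dict]:
    """Build a spheroid micrograph with known fragmentation and viability.

    One main disk sits at the image centre; each requested fragment is a disk
    of approximately the requested area placed disjoint from the main body and
    from other fragments (bounded retries, else :class:`GenerationError`).
    Live and dead channel intensities over structures are ``foreground *
    live_dead_ratio`` and ``foreground``; Gaussian background noise (clipped
    at zero) is added to every channel. Truth reports mask areas, the implied
    disaggregation index and per-channel integrated intensities over the
    structure mask.
    """
    if main_radius_px <= 0:
        raise ConfigError("main_radius_px must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 5)))
    h, w = shape
    center = (h / 2.0, w / 2.0)
    main = _disk_mask(shape, center, main_radius_px)

    placed: list[tuple[float, float, float]] = [(center[0], center[1], main_radius_px)]
    frag_mask = np.zeros(shape, dtype=bool)
    margin = 6.0  # keep structures separated so smoothing cannot merge them
    for area in fragment_areas_px:
        r = float(np.sqrt(float(area) / np.pi))
        if r <= 0:
            raise ConfigError("fragment areas must be positive")
        for _ in range(max_tries):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + margin for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                frag_mask |= _disk_mask(shape, (cy, cx), r)
                break
        else:
            raise GenerationError(
                f"could not place fragment of area {area} after {max_tries} tries"
            )

    structures = main | frag_mask

    def channel(gain):
        img = np.where(structures, gain, 0.0)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        return np.clip(img, 0.0, None)

    chans = {
        "phase": channel(foreground),
        "live": channel(foreground * live_dead_ratio),
        "dead": channel(foreground),
    }
    image = SpheroidImage(chans, pixel_size=None).validate()
    main_area = int(main.sum())
    frag_area = int(frag_mask.sum())
    truth = {
        "main_area_px": main_area,
        "fragment_area_px": frag_area,
        "disaggregation_index": frag_area / main_area,
        "channel_sums": {
            "phase": float(foreground) * (main_area + frag_area),
            "live": float(foreground * live_dead_ratio) * (main_area + frag_area),
            "dead": float(foreground) * (main_area + frag_area),
        },
        "live_dead_ratio": float(live_dead_ratio),
        "n_structures": 1 + len(fragment_areas_px),
    }
    return image, truth


def simulate_nuclei_field(
    n_nuclei: int,
    seed: int,
    radius_px: float = 6.0,
    shape: tuple[int, int] = (512, 512),
    foreground: float = 500.0,
    noise_sd: float = 3.0,
    min_separation: float | None = None,
    max_tries: int = 500,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """A nuclei channel with ``n_nuclei`` disjoint disk nuclei; returns centres."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 6)))
    h, w = shape
    sep = 2 * radius_px + 8.0 if min_separation is None else min_separation
    centers: list[tuple[float, float]] = []
    for _ in range(n_nuclei):
        for _ in range(max_tries):
            cy = rng.uniform(radius_px + 2, h - radius_px - 2)
            cx = rng.uniform(radius_px + 2, w - radius_px - 2)
            if all(np.hypot(cy - py, cx - px) >= sep for py, px in centers):
                centers.append((cy, cx))
                break
        else:
            raise GenerationError("could not place all nuclei without overlap")
    img = np.zeros(shape, dtype=float)
    for cy, cx in centers:
        img[_disk_mask(shape, (cy, cx), radius_px)] = foreground
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=shape), 0.0, None)
    return img, centers
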
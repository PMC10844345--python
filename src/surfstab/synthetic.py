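"""Synthetic two-group cortical cohort with known dynamic-connectivity truth.

The generative model is parcel-level: each atlas parcel carries one latent
signal, and the instantaneous correlation matrix of the latents varies over
time.  A parcel pair (p, q) with baseline coupling b has correlation

    r_pq(t) = b * (1 - a_p m_p(t)) * (1 - a_q m_q(t))

where a_p in [0, 1] is the parcel's modulation amplitude and m_p(t) in
{0, 1} (piecewise regimes) or [0, 1] (sinusoidal) its modulation waveform.
Stationary parcels (a = 0) keep a fixed connectivity profile and therefore
high Kendall's-W stability; modulated parcels reorder their windowed FC maps
over time and lose stability.  Vertex signals are their parcel's latent plus
spatially independent noise, with AR(1) temporal autocorrelation.

The cohort mirrors a patient/control case-control design: patients receive
extra modulation amplitude in designated effect parcels (lower expected
stability there), and a visual-field mean-deviation covariate is drawn with
a target rank correlation to one parcel's per-subject modulation amplitude.
All randomness funnels through a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .surface import ParcellationAtlas, SurfaceMesh, build_icosphere

__all__ = [
    "RegimeConfig",
    "MotionTrace",
    "GroundTruth",
    "Subject",
    "SyntheticCohort",
    "default_mesh",
    "default_atlas",
    "default_config",
    "default_truth",
    "simulate_subject_bold",
    "simulate_motion",
    "simulate_cohort",
]

ROTATION_RADIUS_MM = 50.0  # rotation-to-displacement conversion for FD


@dataclass
class RegimeConfig:
    """Parcel-level coupling graph and temporal-modulation parameters.

    Two interchangeable couplings specifications:

    * ``loadings``: a mapping parcel -> 2-vector of loadings on two latent
      network factors.  The implied coupling graph is r_pq = L_p . L_q
      (every parcel pair with a non-trivial product is functionally
      coupled).  A modulated parcel's loading vector is linearly
      interpolated toward ``alt_loadings[p]`` (default: its own loadings
      swapped between the two factors) by s_p(t) = a_p m_p(t), where a_p in
      [0, 1] is the amplitude and m_p(t) the waveform.  Because C(t) =
      L(t) L(t)' + D with unit diagonal, every instantaneous correlation
      matrix is positive semi-definite by construction — modulation
      *re-routes* a parcel's connectivity between networks, which reorders
      its windowed-FC target ranking and is what Kendall's-W stability is
      sensitive to.
    * ``coupling`` / ``alt_coupling``: explicit (parcel_a, parcel_b, r) edge
      lists; an edge's instantaneous weight mixes baseline and alternative
      graphs by max(s_p, s_q).  PSD is checked numerically at generation.

    ``dwell_s`` is the regime length for piecewise modulation; ``period_s``
    the sinusoid period.
    """

    coupling: tuple = ()
    alt_coupling: tuple = ()
    loadings: dict | None = None
    alt_loadings: dict | None = None
    amplitudes: dict = field(default_factory=dict)
    modulation_form: str = "piecewise"       # piecewise | sinusoidal
    dwell_s: float = 64.0
    period_s: float = 80.0
    noise_sd: float = 0.3
    ar_coef: float = 0.3

    def __post_init__(self) -> None:
        for a in self.amplitudes.values():
            if not (0.0 <= a <= 1.0):
                raise ValueError("modulation amplitudes must lie in [0, 1]")
        if self.modulation_form not in ("piecewise", "sinusoidal"):
            raise ValueError(f"unknown modulation form {self.modulation_form!r}")
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValueError("ar_coef must lie in [0, 1)")

    def with_amplitude(self, parcel: int, amplitude: float) -> "RegimeConfig":
        amps = dict(self.amplitudes)
        amps[parcel] = float(np.clip(amplitude, 0.0, 1.0))
        return replace(self, amplitudes=amps)


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations mm, 3 rotations deg."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be (volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def fd(self) -> np.ndarray:
        """Power-style framewise displacement, mm.

        Sum of absolute backward differences of the six parameters, with
        rotations converted to arc length on a 50 mm sphere; FD[0] = 0.
        """
        p = self.params.copy()
        p[:, 3:] = np.deg2rad(p[:, 3:]) * ROTATION_RADIUS_MM
        d = np.abs(np.diff(p, axis=0)).sum(axis=1)
        return np.concatenate([[0.0], d])

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery checks."""

    effect_parcels: tuple = (2,)
    effect_delta: float = 0.6         # extra patient modulation amplitude
    covariate_parcel: int = 5
    covariate_rho: float = -0.5       # target Spearman rho, md_vf vs modulation
    stationary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 < self.covariate_rho < 1.0):
            raise ValueError("target correlation must lie strictly in (-1, 1)")


@dataclass
class Subject:
    subject_id: str
    group: str                        # patient | control
    bold: "object"                    # BoldSeries
    motion: MotionTrace


@dataclass
class SyntheticCohort:
    subjects: list
    design: pd.DataFrame
    truth: GroundTruth
    mesh: SurfaceMesh
    atlas: ParcellationAtlas
    mask: np.ndarray


# ---------------------------------------------------------------------------
# desk-scale defaults

def default_mesh(radius_mm: float = 100.0) -> SurfaceMesh:
    """162-vertex icosphere, a desk-scale stand-in for a template hemisphere."""
    return build_icosphere(2, radius_mm)


def default_atlas(mesh: SurfaceMesh, n_parcels: int = 12) -> ParcellationAtlas:
    """Parcellation by nearest anchor direction (labels 1..n_parcels).

    Anchors are the vertices of a level-0 icosphere (12 directions) truncated
    to ``n_parcels``; every vertex is labeled, parcels are contiguous.
    """
    anchors = build_icosphere(0, 1.0).coords
    if n_parcels > len(anchors):
        anchors = build_icosphere(1, 1.0).coords
    anchors = anchors[:n_parcels]
    unit = mesh.coords / np.linalg.norm(mesh.coords, axis=1, keepdims=True)
    labels = np.argmax(unit @ anchors.T, axis=1) + 1
    names = {i + 1: f"parcel-{i + 1:02d}" for i in range(n_parcels)}
    nets = {i + 1: ("visual" if i < n_parcels // 2 else "attention")
            for i in range(n_parcels)}
    return ParcellationAtlas(labels, names, nets)


def default_config() -> RegimeConfig:
    """Two-network factor structure for 12 parcels.

    Odd parcels load on network factor 1, even parcels on factor 2, with
    graded loadings (0.85 down to 0.60) plus a small off-network loading
    (0.15), so every parcel has a fully ordered connectivity profile over
    the other parcels.  A modulated parcel swaps its loadings between the
    two factors, flipping its target ordering — the contrast the stability
    statistic detects.
    """
    grades = np.linspace(0.85, 0.60, 6)
    loadings = {}
    for i in range(6):
        loadings[2 * i + 1] = (float(grades[i]), 0.15)
        loadings[2 * i + 2] = (0.15, float(grades[i]))
    return RegimeConfig(loadings=loadings)


def default_truth() -> GroundTruth:
    return GroundTruth()


# ---------------------------------------------------------------------------
# single-subject BOLD

def _modulation_waveforms(parcels: np.ndarray, config: RegimeConfig,
                          n_volumes: int, tr_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """(parcels, volumes) modulation waveform m_p(t) in [0, 1]."""
    t = np.arange(n_volumes) * tr_s
    m = np.zeros((len(parcels), n_volumes))
    if config.modulation_form == "piecewise":
        dwell_vols = max(1, int(round(config.dwell_s / tr_s)))
        n_reg = int(np.ceil(n_volumes / dwell_vols))
        for pi in range(len(parcels)):
            # alternate regimes with a random start phase: guarantees both
            # states are visited, still subject-specific
            start = rng.integers(0, 2)
            states = (np.arange(n_reg) + start) % 2
            m[pi] = np.repeat(states, dwell_vols)[:n_volumes]
    else:
        for pi in range(len(parcels)):
            phase = rng.uniform(0, 2 * np.pi)
            m[pi] = 0.5 * (1.0 + np.sin(2 * np.pi * t / config.period_s + phase))
    return m


def _correlation_matrix(parcels: np.ndarray, config: RegimeConfig,
                        m_col: np.ndarray) -> np.ndarray:
    k = len(parcels)
    index = {p: i for i, p in enumerate(parcels)}
    c = np.eye(k)
    amp = np.array([config.amplitudes.get(int(p), 0.0) for p in parcels])
    s = amp * m_col                            # per-parcel switch level
    if config.loadings is not None:
        load = np.zeros((k, 2))
        for i, p in enumerate(parcels):
            base = np.asarray(config.loadings.get(int(p), (0.0, 0.0)), float)
            alt = np.asarray(
                (config.alt_loadings or {}).get(int(p), base[::-1]), float)
            load[i] = (1.0 - s[i]) * base + s[i] * alt
        c = load @ load.T
        np.fill_diagonal(c, 1.0)
        return c
    for a, b, r in config.coupling:
        if a in index and b in index:
            ia, ib = index[a], index[b]
            w = r * (1.0 - max(s[ia], s[ib]))
            c[ia, ib] += w
            c[ib, ia] += w
    for a, b, r in config.alt_coupling:
        if a in index and b in index:
            ia, ib = index[a], index[b]
            w = r * max(s[ia], s[ib])
            c[ia, ib] += w
            c[ib, ia] += w
    np.fill_diagonal(c, 1.0)
    return c


def simulate_subject_bold(mesh: SurfaceMesh, atlas: ParcellationAtlas,
                          config: RegimeConfig, n_volumes: int = 180,
                          tr_s: float = 2.0, seed: int | tuple = 0):
    """Simulate one subject's vertex x timepoint BOLD-like series.

    Latent parcel signals are drawn from the time-varying coupling model
    (innovations from N(0, C(t)) with AR(1) filtering); each vertex gets its
    parcel's latent plus independent Gaussian noise.  Deterministic given the
    seed.  Raises if any implied correlation matrix is not positive
    semi-definite, naming the offending volume.
    """
    from .stability import BoldSeries  # local import avoids a cycle

    if n_volumes < 4:
        raise ValueError("n_volumes too small")
    rng = np.random.default_rng(seed)
    parcels = atlas.parcels
    k = len(parcels)
    m = _modulation_waveforms(parcels, config, n_volumes, tr_s, rng)

    # distinct modulation columns -> cached Cholesky factors
    chol_cache: dict[bytes, np.ndarray] = {}
    innovations = np.empty((k, n_volumes))
    z = rng.standard_normal((k, n_volumes))
    for t_i in range(n_volumes):
        key = m[:, t_i].tobytes()
        if key not in chol_cache:
            c = _correlation_matrix(parcels, config, m[:, t_i])
            eigmin = np.linalg.eigvalsh(c).min()
            if eigmin < -1e-10:
                raise ValueError(
                    f"requested coupling is not positive semi-definite at "
                    f"volume {t_i} (min eigenvalue {eigmin:.3g})")
            chol_cache[key] = np.linalg.cholesky(
                c + 1e-12 * np.eye(k))
        innovations[:, t_i] = chol_cache[key] @ z[:, t_i]

    phi = config.ar_coef
    latents = np.empty_like(innovations)
    latents[:, 0] = innovations[:, 0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t_i in range(1, n_volumes):
        latents[:, t_i] = phi * latents[:, t_i - 1] + scale * innovations[:, t_i]

    index = {p: i for i, p in enumerate(parcels)}
    signal = np.empty((mesh.n_vertices, n_volumes))
    noise = rng.standard_normal(signal.shape) * config.noise_sd
    for v in range(mesh.n_vertices):
        lab = int(atlas.labels[v])
        signal[v] = (latents[index[lab]] if lab in index else 0.0) + noise[v]
    return BoldSeries(signal, tr_s)


def simulate_motion(n_volumes: int, severity: float = 1.0,
                    seed: int | tuple = 0) -> MotionTrace:
    """Random-walk rigid-body motion; per-step SD = 0.02 * severity
    (mm for translations, degrees for rotations)."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6)) * (0.02 * severity)
    steps[0] = 0.0
    return MotionTrace(np.cumsum(steps, axis=0))


# ---------------------------------------------------------------------------
# cohort

def _spearman_to_pearson(rho: float) -> float:
    # bivariate-normal relation: rho_s = (6/pi) asin(r/2)
    return 2.0 * np.sin(np.pi * rho / 6.0)


def simulate_cohort(n_per_group: int = 15,
                    truth: GroundTruth | None = None,
                    config: RegimeConfig | None = None,
                    seed: int = 0,
                    mesh: SurfaceMesh | None = None,
                    atlas: ParcellationAtlas | None = None,
                    n_volumes: int = 180, tr_s: float = 2.0,
                    motion_severity: float = 1.0) -> SyntheticCohort:
    """Simulate a patient/control cohort with injected stability effects.

    Patients receive ``truth.effect_delta`` extra modulation amplitude in the
    effect parcels.  Every subject additionally gets an individual modulation
    amplitude in the covariate parcel; patients' visual-field mean deviation
    (md_vf, dB) is drawn so that its rank correlation with that amplitude
    approaches ``truth.covariate_rho``.  Per-subject seeds are derived
    deterministically from the master seed.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    truth = truth or default_truth()
    config = config or default_config()
    mesh = mesh or default_mesh()
    atlas = atlas or default_atlas(mesh)
    for p in truth.effect_parcels + (truth.covariate_parcel,):
        if p not in atlas.parcels:
            raise ValueError(f"ground-truth parcel {p} absent from atlas")

    rng = np.random.default_rng([seed, 0x5AB1E])
    n_total = 2 * n_per_group
    groups = ["patient"] * n_per_group + ["control"] * n_per_group

    # per-subject covariate-parcel modulation amplitude
    cov_amp = rng.uniform(0.2, 0.8, size=n_total)
    # md_vf: rank-correlated with the patients' covariate-parcel amplitude
    r_pearson = _spearman_to_pearson(truth.covariate_rho)
    z_amp = (cov_amp - 0.5) / np.sqrt(1.0 / 12.0) / 0.6  # standardised U(0.2,0.8)
    latent = r_pearson * z_amp + np.sqrt(1 - r_pearson ** 2) * rng.standard_normal(n_total)
    md_vf = np.clip(-7.5 + 6.0 * latent, -32.0, 1.7)

    ages = np.round(rng.uniform(21, 72, size=n_total)).astype(int)
    sexes = rng.choice(["male", "female"], size=n_total, p=[0.58, 0.42])

    subjects = []
    rows = []
    stationary = {int(p): config.amplitudes.get(int(p), 0.0) == 0.0
                  for p in atlas.parcels}
    truth = replace(truth, stationary=stationary)
    for i in range(n_total):
        cfg = config.with_amplitude(truth.covariate_parcel, cov_amp[i])
        if groups[i] == "patient":
            for p in truth.effect_parcels:
                base = cfg.amplitudes.get(int(p), 0.0)
                cfg = cfg.with_amplitude(int(p), base + truth.effect_delta)
        bold = simulate_subject_bold(mesh, atlas, cfg, n_volumes, tr_s,
                                     seed=(seed, 1, i))
        motion = simulate_motion(n_volumes, motion_severity, seed=(seed, 2, i))
        sid = f"sub-{i + 1:03d}"
        bold.subject_id = sid
        subjects.append(Subject(sid, groups[i], bold, motion))
        rows.append({
            "subject": sid, "group": groups[i], "age": ages[i],
            "sex": sexes[i], "mean_fd": motion.mean_fd,
            "md_vf": md_vf[i] if groups[i] == "patient" else np.nan,
            "covariate_amplitude": cov_amp[i],
        })
    design = pd.DataFrame(rows)
    mask = np.ones(mesh.n_vertices, dtype=bool)
    return SyntheticCohort(subjects, design, truth, mesh, atlas, mask)
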
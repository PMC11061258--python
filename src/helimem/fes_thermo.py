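"""Well-tempered metadynamics post-processing and adsorption thermodynamics.

Pipeline: deposited Gaussian bias records (HILLS dialect, one file per
walker) are summed into a 2D free-energy surface W(z, cos phi); the surface
is projected onto one collective variable by Boltzmann-weighted integration,

    W1(s) = -(1/beta) ln INT exp(-beta W(s, u)) du,

anchored to zero in the far-field (free) region; and the adsorption
equilibrium is quantified by the partition coefficient

    kappa = 1/(2 lambda) INT_0^lambda INT_-1^1 exp(-beta W(z, c)) dz dc    (2D)
    kappa = 1/lambda     INT_0^lambda        exp(-beta W(z))      dz      (1D)

where lambda is the z-distance beyond which the peptide-membrane interaction
is negligible.  The 1 M standard state (volume per molecule V0 = 1.660 nm^3)
gives kappa0 = kappa * lambda / V0^(1/3) and DG0 = -kT ln kappa0; the
difference of DG0 between two membranes is the transfer free energy DDG0,
independent of any common aqueous-phase offset.

All Boltzmann integrals use composite trapezoid weights inside a
log-sum-exp, so deep minima (hundreds of kT) cannot overflow.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from ._constants import (
    DEFAULT_TEMPERATURE_K,
    DEFAULT_V0_NM3,
    DEFAULT_WALL_BOUNDS_NM,
    DEFAULT_WALL_KAPPA,
    KB_KJ_PER_MOL_K,
)
from .core import (
    CVAxis,
    FESGrid,
    HillsRecord,
    InputError,
    NumericalError,
    PMFProfile,
    ValidationError,
)

__all__ = [
    "ThermoResult",
    "TransferResult",
    "read_hills",
    "write_hills",
    "read_fes_grid",
    "write_fes_grid",
    "reconstruct_fes",
    "project_to_1d",
    "anchor_profile",
    "kappa_from_2d",
    "kappa_from_1d",
    "standard_state",
    "transfer_ddg",
    "choose_lambda",
    "convergence_blocks",
    "dg0_uncertainty",
    "wall_bias",
]


@dataclass
class ThermoResult:
    """Partition coefficient and standard adsorption free energy."""

    kappa: float
    kappa0: float
    lam: float  # nm
    V0: float  # nm^3
    dG0: float  # kJ/mol
    temperature: float  # K
    beta: float  # mol/kJ
    method: str  # 'eq_2d' | 'eq_1d'
    uncertainty: float | None = None  # kJ/mol on dG0

    def __post_init__(self):
        if self.kappa <= 0 or self.lam <= 0 or self.V0 <= 0:
            raise ValidationError("kappa, lambda and V0 must be positive")
        expected = -np.log(self.kappa0) / self.beta
        if abs(self.dG0 - expected) > 1e-9:
            raise ValidationError("dG0 inconsistent with -kT ln(kappa0)")

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "kappa0": self.kappa0,
            "lambda_nm": self.lam,
            "V0_nm3": self.V0,
            "dG0_kJ_mol": self.dG0,
            "temperature_K": self.temperature,
            "method": self.method,
            "uncertainty_kJ_mol": self.uncertainty,
        }


@dataclass(frozen=True)
class TransferResult:
    """Membrane-to-membrane transfer free energy DDG0 = DG0_C - DG0_M."""

    ddG0: float  # kJ/mol
    from_membrane: str
    to_membrane: str


# ---------------------------------------------------------------- HILLS I/O

def read_hills(paths) -> HillsRecord:
    """Read one HILLS file per walker and merge them, sorted by time.

    Dialect: a header line ``#! FIELDS time <cv...> sigma_<cv...> height
    biasf`` followed by whitespace-separated columns.  All walkers must share
    the same CV set.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "read"):
        paths = [paths]
    paths = list(paths)
    if not paths:
        return HillsRecord([], np.empty(0), np.empty((0, 1)), np.empty((0, 1)),
                           np.empty(0), 0.0, np.empty(0, dtype=int))
    cv_names = None
    times, centers, sigmas, heights, walkers = [], [], [], [], []
    biasf = 0.0
    for walker, path in enumerate(paths):
        with open(path) as fh:
            lines = fh.readlines()
        header = next((l for l in lines if l.startswith("#!")), None)
        if header is None:
            raise InputError(f"{path}: missing '#! FIELDS ...' header")
        fields = header.split()[2:]
        if fields[0] != "time" or "height" not in fields:
            raise InputError(f"{path}: malformed FIELDS header {fields}")
        h_idx = fields.index("height")
        names = fields[1:h_idx]
        ncv = len(names) // 2
        file_cvs = names[:ncv]
        if [f"sigma_{c}" for c in file_cvs] != names[ncv:]:
            raise InputError(f"{path}: center/sigma columns inconsistent: {names}")
        if cv_names is None:
            cv_names = file_cvs
        elif file_cvs != cv_names:
            raise InputError(
                f"{path}: CV set {file_cvs} differs from {cv_names} of first walker"
            )
        has_biasf = "biasf" in fields
        bf_idx = fields.index("biasf") if has_biasf else None
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = [float(x) for x in line.split()]
            times.append(cols[0])
            centers.append(cols[1 : 1 + ncv])
            sig = cols[1 + ncv : 1 + 2 * ncv]
            if any(s < 0 for s in sig):
                raise InputError(f"{path}: negative Gaussian width {sig}")
            sigmas.append(sig)
            heights.append(cols[h_idx])
            if has_biasf:
                biasf = cols[bf_idx]
            walkers.append(walker)
    if not times:
        return HillsRecord(cv_names or [], np.empty(0), np.empty((0, 1)),
                           np.empty((0, 1)), np.empty(0), biasf,
                           np.empty(0, dtype=int))
    order = np.argsort(np.asarray(times), kind="stable")
    return HillsRecord(
        cv_names,
        np.asarray(times)[order],
        np.asarray(centers)[order],
        np.asarray(sigmas)[order],
        np.asarray(heights)[order],
        biasf,
        np.asarray(walkers, dtype=int)[order],
    )


def write_hills(record: HillsRecord, path, walker_id: int | None = None) -> None:
    """Write (a walker slice of) a hills record in the HILLS dialect."""
    sel = np.ones(record.n_hills, dtype=bool)
    if walker_id is not None:
        sel = record.walker_ids == walker_id
    cvs = record.cv_names
    with open(path, "w") as fh:
        fh.write(
            "#! FIELDS time "
            + " ".join(cvs)
            + " "
            + " ".join(f"sigma_{c}" for c in cvs)
            + " height biasf\n"
        )
        for i in np.nonzero(sel)[0]:
            row = [record.times[i], *record.centers[i], *record.sigmas[i],
                   record.heights[i], record.bias_factor]
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


# ------------------------------------------------------------- FES grid I/O

def write_fes_grid(fes: FESGrid, path) -> None:
    """Row-major text dump with a commented axis header."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K {fes.temperature}\n")
        fh.write(f"# bias_factor {fes.bias_factor}\n")
        for ax in fes.axes:
            fh.write(
                f"# axis {ax.name} unit={ax.unit or '-'} n={ax.values.size} "
                f"periodic={int(ax.periodic)} period={ax.period}\n"
            )
        mesh = np.meshgrid(*[ax.values for ax in fes.axes], indexing="ij")
        cols = [m.ravel() for m in mesh] + [fes.values.ravel()]
        for row in zip(*cols):
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_fes_grid(path) -> FESGrid:
    temperature, bias_factor = DEFAULT_TEMPERATURE_K, 0.0
    axes_meta = []
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "temperature_K":
                    temperature = float(parts[1])
                elif parts and parts[0] == "bias_factor":
                    bias_factor = float(parts[1])
                elif parts and parts[0] == "axis":
                    meta = dict(p.split("=") for p in parts[2:])
                    axes_meta.append(
                        (parts[1], meta.get("unit", ""), int(meta["n"]),
                         bool(int(meta["periodic"])), float(meta["period"]))
                    )
                continue
            data.append([float(x) for x in line.split()])
    if not axes_meta:
        raise InputError(f"{path}: no '# axis' header lines")
    arr = np.asarray(data)
    shape = tuple(n for _, _, n, _, _ in axes_meta)
    axes = []
    for dim, (name, unit, n, periodic, period) in enumerate(axes_meta):
        col = arr[:, dim].reshape(shape)
        sl = tuple(0 if d != dim else slice(None) for d in range(len(shape)))
        axes.append(CVAxis(name, col[sl], periodic=periodic, period=period,
                           unit="" if unit == "-" else unit))
    return FESGrid(axes, arr[:, -1].reshape(shape), temperature, bias_factor)


# --------------------------------------------------------- FES reconstruction

def reconstruct_fes(
    hills: HillsRecord,
    grid_spec: dict,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tempered_heights: bool = True,
    n_periodic_images: int = 1,
) -> FESGrid:
    """Sum deposited Gaussians into a free-energy surface.

    ``grid_spec`` maps each CV name to ``(min, max, n_points)`` or
    ``(min, max, n_points, period)`` for a periodic axis.  With the common
    on-disk convention of already-tempered heights, the estimate is
    FES = -(gamma/(gamma-1)) * sum of Gaussians, shifted so min(FES) = 0;
    ``tempered_heights=False`` switches to the un-tempered convention
    FES = -((gamma-1)/gamma) * sum.
    """
    gamma = hills.bias_factor
    axes = []
    for name in hills.cv_names or list(grid_spec):
        if name not in grid_spec:
            raise ValidationError(f"grid_spec missing axis {name!r}")
        spec = grid_spec[name]
        lo, hi, n = spec[0], spec[1], int(spec[2])
        period = float(spec[3]) if len(spec) > 3 else 0.0
        axes.append(CVAxis(name, np.linspace(lo, hi, n),
                           periodic=period > 0, period=period))
    shape = tuple(ax.values.size for ax in axes)
    bias = np.zeros(shape)
    if hills.n_hills:
        if gamma <= 1:
            raise ValidationError(f"bias factor must exceed 1, got {gamma}")
        uncovered = 0
        for d, ax in enumerate(axes):
            c = hills.centers[:, d]
            if not ax.periodic:
                margin = 4.0 * hills.sigmas[:, d]
                uncovered += int(np.sum((c - margin < ax.values[0] - 1e-9)
                                        | (c + margin > ax.values[-1] + 1e-9)))
        if uncovered:
            warnings.warn(
                f"{uncovered} hill(s) extend beyond the grid by > 4 sigma; "
                "their tails are truncated", stacklevel=2)
        mesh = np.meshgrid(*[ax.values for ax in axes], indexing="ij")
        flat = [m.ravel() for m in mesh]
        total = np.zeros(flat[0].size)
        chunk = 256
        for start in range(0, hills.n_hills, chunk):
            sl = slice(start, min(start + chunk, hills.n_hills))
            expo = np.zeros((hills.heights[sl].size, flat[0].size))
            for d, ax in enumerate(axes):
                delta = flat[d][None, :] - hills.centers[sl, d][:, None]
                if ax.periodic:
                    delta -= ax.period * np.round(delta / ax.period)
                expo += (delta / hills.sigmas[sl, d][:, None]) ** 2
            total += hills.heights[sl] @ np.exp(-0.5 * expo)
        bias = total.reshape(shape)
    factor = gamma / (gamma - 1.0) if (hills.n_hills and tempered_heights) else (
        (gamma - 1.0) / gamma if hills.n_hills else 1.0)
    values = -factor * bias
    values -= values.min()
    return FESGrid(axes, values, temperature=temperature, bias_factor=gamma)


# ------------------------------------------------------------- projections

def project_to_1d(fes: FESGrid, keep_axis: str, temperature: float | None = None) -> PMFProfile:
    """Boltzmann-project a 2D surface onto one CV (log-sum-exp trapezoid)."""
    if len(fes.axes) != 2:
        raise ValidationError("projection requires exactly 2 axes")
    temperature = temperature or fes.temperature
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    keep = fes.axis(keep_axis)
    other = 1 - keep
    u = fes.axes[other].values
    w_trap = np.gradient(u)
    w_trap[0] = 0.5 * (u[1] - u[0])
    w_trap[-1] = 0.5 * (u[-1] - u[-2])
    vals = np.moveaxis(fes.values, keep, 0)  # (keep, other)
    log_int = logsumexp(-beta * vals, axis=1, b=w_trap[None, :])
    profile = -log_int / beta
    profile -= profile.min()
    return PMFProfile(fes.axes[keep].name, fes.axes[keep].values.copy(), profile)


def anchor_profile(pmf: PMFProfile, window: tuple[float, float],
                   flatness_tol_kt: float = 0.25,
                   temperature: float = DEFAULT_TEMPERATURE_K) -> PMFProfile:
    """Shift a PMF so its mean over ``window`` is zero; warn if not flat."""
    mask = (pmf.grid >= window[0] - 1e-12) & (pmf.grid <= window[1] + 1e-12)
    if not mask.any():
        raise ValidationError(f"reference window {window} off the grid")
    ref = pmf.values[mask]
    kt = KB_KJ_PER_MOL_K * temperature
    if np.max(np.abs(ref - ref.mean())) > flatness_tol_kt * kt:
        warnings.warn(
            f"far-field plateau not flat within {flatness_tol_kt} kT over "
            f"{window}; anchoring may bias kappa", stacklevel=2)
    return replace(pmf, values=pmf.values - ref.mean(), reference_window=window)


# ------------------------------------------------------------ partition kappa

def _restrict_to_lambda(z: np.ndarray, integrand_log: np.ndarray, lam: float):
    """Trapezoid grid on [0, lambda], linearly interpolating the boundary."""
    if lam < z[0] - 1e-12 or lam > z[-1] + 1e-12:
        raise ValidationError(f"lambda={lam} nm outside grid [{z[0]}, {z[-1]}]")
    mask = z <= lam + 1e-12
    zi = z[mask]
    fi = integrand_log[mask] if integrand_log.ndim == 1 else integrand_log[mask, :]
    if zi[-1] < lam - 1e-12:
        j = np.searchsorted(z, lam)
        wgt = (lam - z[j - 1]) / (z[j] - z[j - 1])
        f_b = (1 - wgt) * integrand_log[j - 1] + wgt * integrand_log[j]
        zi = np.append(zi, lam)
        fi = np.concatenate([fi, f_b[None] if fi.ndim > 1 else [f_b]])
    return zi, fi


def _anchored_2d(fes: FESGrid, lam: float, temperature: float) -> np.ndarray:
    """Return W(z, c) shifted so the free region z >= lambda averages zero."""
    iz = fes.axis("z")
    z = fes.axes[iz].values
    w = np.moveaxis(fes.values, iz, 0)
    free = z >= lam - 1e-12
    if not free.any():
        raise ValidationError("grid has no free region beyond lambda")
    ref = w[free].mean()
    kt = KB_KJ_PER_MOL_K * temperature
    if np.max(np.abs(w[free] - ref)) > 0.25 * kt:
        warnings.warn("free region beyond lambda not flat within 0.25 kT",
                      stacklevel=3)
    return w - ref


def kappa_from_2d(
    fes: FESGrid,
    lam: float,
    temperature: float | None = None,
    V0: float = DEFAULT_V0_NM3,
    anchor: bool = True,
) -> ThermoResult:
    """kappa = 1/(2 lambda) INT_0^lambda INT_-1^1 e^(-beta W(z,c)) dz dc.

    The cos(tilt) measure has width 2, hence the 1/(2 lambda) normalisation;
    a flat W = 0 surface gives kappa = 1 exactly.  The surface is anchored so
    the free region (z >= lambda) averages zero unless ``anchor=False``.
    """
    temperature = temperature or fes.temperature
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    iz = fes.axis("z")
    z = fes.axes[iz].values
    c = fes.axes[1 - iz].values
    w = _anchored_2d(fes, lam, temperature) if anchor else np.moveaxis(fes.values, iz, 0)
    # inner trapezoid over cos(tilt) in log space, then over z
    wc = np.gradient(c)
    wc[0] = 0.5 * (c[1] - c[0])
    wc[-1] = 0.5 * (c[-1] - c[-2])
    log_inner = logsumexp(-beta * w, axis=1, b=wc[None, :])  # per z
    zi, fi = _restrict_to_lambda(z, log_inner, lam)
    wz = np.gradient(zi)
    wz[0] = 0.5 * (zi[1] - zi[0])
    wz[-1] = 0.5 * (zi[-1] - zi[-2])
    log_kappa = logsumexp(fi, b=wz) - np.log(2.0 * lam)
    return standard_state(
        _bare_result(np.exp(log_kappa), lam, temperature, "eq_2d"), V0
    )


def kappa_from_1d(
    pmf: PMFProfile,
    lam: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    V0: float = DEFAULT_V0_NM3,
    anchor: bool = True,
) -> ThermoResult:
    """kappa = 1/lambda INT_0^lambda e^(-beta W(z)) dz on an anchored PMF."""
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    z = pmf.grid
    if anchor:
        pmf = anchor_profile(pmf, (lam, float(z[-1])), temperature=temperature)
    zi, fi = _restrict_to_lambda(z, -beta * pmf.values, lam)
    wz = np.gradient(zi)
    wz[0] = 0.5 * (zi[1] - zi[0])
    wz[-1] = 0.5 * (zi[-1] - zi[-2])
    log_kappa = logsumexp(fi, b=wz) - np.log(lam)
    return standard_state(
        _bare_result(np.exp(log_kappa), lam, temperature, "eq_1d"), V0
    )


def _bare_result(kappa: float, lam: float, temperature: float, method: str) -> ThermoResult:
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    v0 = DEFAULT_V0_NM3
    kappa0 = kappa * lam / v0 ** (1.0 / 3.0)
    return ThermoResult(kappa, kappa0, lam, v0, -np.log(kappa0) / beta,
                        temperature, beta, method)


def standard_state(result: ThermoResult, V0: float = DEFAULT_V0_NM3) -> ThermoResult:
    """Rescale to the 1 M standard state: kappa0 = kappa lambda / V0^(1/3)."""
    if V0 <= 0:
        raise ValidationError("V0 must be positive")
    kappa0 = result.kappa * result.lam / V0 ** (1.0 / 3.0)
    dG0 = -np.log(kappa0) / result.beta
    return replace(result, kappa0=kappa0, V0=V0, dG0=dG0)


def transfer_ddg(result_M: ThermoResult, result_C: ThermoResult,
                 from_membrane: str = "M", to_membrane: str = "C") -> TransferResult:
    """DDG0 = DG0_C - DG0_M: preference of the peptide for membrane C over M."""
    if abs(result_M.temperature - result_C.temperature) > 1e-9:
        raise ValidationError("results at different temperatures")
    if abs(result_M.V0 - result_C.V0) > 1e-12:
        raise ValidationError("results at different standard-state volumes")
    return TransferResult(result_C.dG0 - result_M.dG0, from_membrane, to_membrane)


def choose_lambda(pmf: PMFProfile, threshold: float | None = None,
                  temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Smallest z beyond which |W| stays below a threshold (default 0.5 kT).

    Requires the profile to actually reach a flat far field; raises with a
    diagnostic otherwise.
    """
    if threshold is None:
        threshold = 0.5 * KB_KJ_PER_MOL_K * temperature
    above = np.abs(pmf.values) >= threshold
    if above[-1]:
        raise ValidationError(
            f"no far-field plateau: |W|={abs(pmf.values[-1]):.3g} kJ/mol at "
            f"z={pmf.grid[-1]:.3g} nm exceeds threshold {threshold:.3g}"
        )
    if not above.any():
        return float(pmf.grid[0])
    last = np.nonzero(above)[0][-1]
    return float(pmf.grid[last + 1])


def convergence_blocks(profiles: list[PMFProfile], trailing_fraction: float = 0.3) -> np.ndarray:
    """Pointwise std of the trailing-fraction profiles, each re-anchored.

    The profiles are time-ordered PMF snapshots; the spread of the last
    ``trailing_fraction`` of them estimates the pointwise uncertainty.
    """
    if not 0 < trailing_fraction <= 1:
        raise ValidationError("trailing_fraction must be in (0, 1]")
    n_keep = max(1, int(round(trailing_fraction * len(profiles))))
    trailing = profiles[-n_keep:]
    if len(trailing) < 3:
        raise ValidationError(f"need >= 3 trailing profiles, got {len(trailing)}")
    grid = trailing[0].grid
    ref_window = trailing[0].reference_window
    stack = []
    for p in trailing:
        if p.grid.shape != grid.shape or not np.allclose(p.grid, grid):
            raise ValidationError("profiles must share one axis grid")
        vals = p.values
        if ref_window is not None:
            mask = (grid >= ref_window[0]) & (grid <= ref_window[1])
            vals = vals - vals[mask].mean()
        stack.append(vals)
    return np.std(np.asarray(stack), axis=0, ddof=1)


def dg0_uncertainty(profiles: list[PMFProfile], lam: float,
                    temperature: float = DEFAULT_TEMPERATURE_K,
                    V0: float = DEFAULT_V0_NM3,
                    trailing_fraction: float = 0.3) -> float:
    """Std of DG0 recomputed on each trailing-block PMF snapshot."""
    n_keep = max(1, int(round(trailing_fraction * len(profiles))))
    trailing = profiles[-n_keep:]
    if len(trailing) < 3:
        raise ValidationError(f"need >= 3 trailing profiles, got {len(trailing)}")
    dgs = [kappa_from_1d(p, lam, temperature, V0).dG0 for p in trailing]
    return float(np.std(dgs, ddof=1))


def wall_bias(z, bounds: tuple[float, float] = DEFAULT_WALL_BOUNDS_NM,
              kappa_wall: float = DEFAULT_WALL_KAPPA):
    """Half-harmonic sampling walls: (kappa/2)(z - bound)^2 outside [lo, hi].

    Total function (never raises); used both to emulate restricted sampling
    in synthetic depositions and to mask wall-contaminated grid regions.
    """
    lo, hi = bounds
    if lo > hi:
        raise ValidationError("wall bounds must be ordered")
    z = np.asarray(z, dtype=float)
    below = np.where(z < lo, z - lo, 0.0)
    above = np.where(z > hi, z - hi, 0.0)
    out = 0.5 * kappa_wall * (below**2 + above**2)
    return float(out) if out.ndim == 0 else out
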
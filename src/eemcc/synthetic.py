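"""Seed-deterministic generators for every statistical structure the
analysis assumes.

* harmonic ensembles with known spring constants (vibrational oracle);
* dihedral series with prescribed conformer populations;
* water-shell donor/acceptor event streams with prescribed biases;
* an overdamped-Langevin toy well-tempered metadynamics sampler on
  analytic 1-D potentials, emitting the exact deposited bias per frame;
* a small geometric solution ensemble (proteins, excipient, ions,
  waters) for end-to-end runs of the shell/classification/contact and
  energy machinery.

Every generator takes an integer seed and returns identical output for
identical inputs; ensembles and topologies can be written in the
package's file dialects so the CLI pipeline runs on generator output
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .constants import KB_KJ_MOL
from .frames import FrameEnsemble
from .neighbourhood import ShellObservation
from .topology import Topology


def _maxwell_ke(rng: np.random.Generator, kBT: float, shape) -> np.ndarray:
    """Kinetic energy per atom: (kBT/2) * chi-squared with 3 dof."""
    return 0.5 * kBT * rng.chisquare(3, size=shape)


def _monatomic_topology(
    n: int,
    mass: float,
    charge: float,
    species: str,
    element: str = "X",
    formal_charge: float = 0.0,
) -> Topology:
    return Topology(
        element=np.array([element] * n, dtype=object),
        name=np.array([element] * n, dtype=object),
        mass=np.full(n, float(mass)),
        charge=np.full(n, float(charge)),
        ua_id=np.arange(n),
        monomer_id=np.arange(n),
        molecule_id=np.arange(n),
        bonds=np.empty((0, 2), dtype=int),
        monomer_class={i: "n/a" for i in range(n)},
        species={i: species for i in range(n)},
        formal_charge={i: formal_charge for i in range(n)},
    )


def gen_harmonic_ensemble(
    n_units: int = 1,
    k: float = 10.0,
    m: float = 18.0,
    T: float = 298.0,
    n_frames: int = 5000,
    seed: int = 0,
    species: str = "cation",
    box: float = 50.0,
    spacing: float = 10.0,
) -> tuple[FrameEnsemble, Topology]:
    """Independent 3-D isotropic harmonic units at exact Boltzmann statistics.

    Each monatomic unit fluctuates about a lattice site with spring
    constant ``k`` (kJ mol^-1 A^-2): positions are Gaussian with
    variance kB*T/k per axis, forces are -k*dx (force variance
    k*kB*T per axis), U = |F|^2 / 2k and K is Maxwell-Boltzmann.
    Units are declared at their highest level (monatomic molecules) so
    no mode removal applies.
    """
    rng = np.random.default_rng(seed)
    kBT = KB_KJ_MOL * T
    sites = (np.arange(n_units)[:, None] * np.array([spacing, 0.0, 0.0])
             + box / 2)
    dx = rng.normal(0.0, np.sqrt(kBT / k), size=(n_frames, n_units, 3))
    positions = sites[None] + dx
    forces = -k * dx
    pe = 0.5 * k * np.sum(dx**2, axis=2)
    ke = _maxwell_ke(rng, kBT, (n_frames, n_units))
    ens = FrameEnsemble(
        times=np.arange(n_frames, dtype=float),
        box=np.full((n_frames, 3), float(box)),
        positions=positions,
        forces=forces,
        pe=pe,
        ke=ke,
    )
    ens.validate()
    top = _monatomic_topology(n_units, m, 0.0, species)
    return ens, top


def gen_dihedral_series(
    populations: np.ndarray,
    centers: np.ndarray | None = None,
    kappa: float = 50.0,
    n_frames: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    """Angles (deg, in [-180, 180)) from a von Mises mixture.

    ``populations`` must sum to 1; default peak centres are the
    staggered rotamer positions -60, 60, 180 degrees.
    """
    populations = np.asarray(populations, dtype=float)
    if abs(populations.sum() - 1.0) > 1e-9:
        raise ValueError("conformer populations must sum to 1")
    if centers is None:
        centers = np.array([-60.0, 60.0, 180.0])[: len(populations)]
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(populations), size=n_frames, p=populations)
    ang = rng.vonmises(np.deg2rad(centers)[comp], kappa)
    deg = np.rad2deg(ang)
    return (deg + 180.0) % 360.0 - 180.0


def gen_water_shells(
    shell_spec: dict[str, tuple[int, float, float]],
    n_frames: int = 2000,
    n_waters: int = 10,
    n_donate: int = 2,
    n_accept: int = 2,
    seed: int = 0,
) -> list[ShellObservation]:
    """Label-level shell/hydrogen-bond event streams with prescribed biases.

    ``shell_spec`` maps neighbour label -> (N_i, donate weight, accept
    weight); per water per frame the shell holds exactly N_i neighbours
    of each label, ``n_donate`` donation events are drawn with
    probability proportional to the donate weights and ``n_accept``
    acceptance events proportional to the accept weights (no events if
    all weights vanish).  Observations feed the same accumulator as the
    geometric pathway.
    """
    labels = sorted(shell_spec)
    rng = np.random.default_rng(seed)
    shell = tuple(sorted(
        lab for lab in labels for _ in range(shell_spec[lab][0])
    ))
    pd_w = np.array([shell_spec[lab][1] for lab in labels], dtype=float)
    pa_w = np.array([shell_spec[lab][2] for lab in labels], dtype=float)
    obs = []
    for f in range(n_frames):
        for w in range(n_waters):
            donated = accepted = ()
            if pd_w.sum() > 0:
                donated = tuple(
                    labels[i] for i in
                    rng.choice(len(labels), size=n_donate, p=pd_w / pd_w.sum())
                )
            if pa_w.sum() > 0:
                accepted = tuple(
                    labels[i] for i in
                    rng.choice(len(labels), size=n_accept, p=pa_w / pa_w.sum())
                )
            obs.append(ShellObservation(
                shell_labels=shell, donated=donated, accepted=accepted,
                water=w, frame=f,
            ))
    return obs


# ---------------------------------------------------------------------------
# toy well-tempered metadynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWell:
    """U(s) = barrier*(s^2-1)^2 + delta*s/2; minima near s = +-1.

    ``delta`` is the potential-energy difference U(+1) - U(-1) in
    kJ mol^-1 (the well asymmetry).
    """

    barrier: float = 7.4
    delta: float = 0.0

    def U(self, s):
        return self.barrier * (np.asarray(s) ** 2 - 1) ** 2 + 0.5 * self.delta * s

    def dU(self, s):
        return 4 * self.barrier * s * (np.asarray(s) ** 2 - 1) + 0.5 * self.delta

    def population_right(self, T: float = 298.0, lim: float = 3.0) -> float:
        """Boltzmann probability of the s > 0 well (numerical quadrature)."""
        beta = 1.0 / (KB_KJ_MOL * T)
        z_r = quad(lambda s: np.exp(-beta * self.U(s)), 0.0, lim)[0]
        z_l = quad(lambda s: np.exp(-beta * self.U(s)), -lim, 0.0)[0]
        return z_r / (z_l + z_r)


@dataclass
class WTMTDResult:
    """Frames of the toy sampler with the exact bias at each frame time."""

    times: np.ndarray
    s: np.ndarray
    bias: np.ndarray  # V(s_t, t), kJ mol^-1
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: float = 0.0
    gamma: float = 0.0

    def free_energy_profile(self, s: np.ndarray) -> np.ndarray:
        """Free energy read from the converged bias.

        The well-tempered bias converges to -(1 - 1/gamma) * G(s) + C,
        so G(s) = -gamma/(gamma - 1) * V(s) up to a constant.
        """
        return -self.gamma / (self.gamma - 1.0) * self.final_bias(s)

    def final_bias(self, s: np.ndarray) -> np.ndarray:
        """Accumulated bias profile V(s) after the last deposition."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(self.centers) == 0:
            return np.zeros_like(s)
        g = np.exp(-((s[:, None] - self.centers[None, :]) ** 2)
                   / (2 * self.sigma**2))
        return g @ self.heights


def toy_wtmtd(
    potential: DoubleWell,
    W0: float = 1.5,
    sigma: float = 0.2,
    stride: int = 500,
    gamma: float = 20.0,
    T: float = 298.0,
    dt: float = 0.005,
    friction: float = 1.0,
    n_steps: int = 400_000,
    save_stride: int = 50,
    s0: float = -1.0,
    seed: int = 0,
) -> WTMTDResult:
    """Overdamped-Langevin well-tempered metadynamics on a 1-D potential.

    Gaussians of width ``sigma`` are deposited every ``stride`` steps
    with the tempered height W0 * exp(-V(s_dep)/(kB*dT)) where
    dT = (gamma - 1) * T.  With W0 = 0 the bias is identically zero and
    the run degenerates to plain Langevin sampling.
    """
    if gamma <= 1:
        raise ValueError("bias factor gamma must exceed 1")
    rng = np.random.default_rng(seed)
    kBT = KB_KJ_MOL * T
    dT = (gamma - 1.0) * T
    kBdT = KB_KJ_MOL * dT
    noise_scale = np.sqrt(2 * kBT * dt / friction)

    centers: list[float] = []
    heights: list[float] = []
    c_arr = np.empty(0)
    h_arr = np.empty(0)

    def bias_and_grad(s: float) -> tuple[float, float]:
        if len(c_arr) == 0:
            return 0.0, 0.0
        d = s - c_arr
        g = h_arr * np.exp(-d**2 / (2 * sigma**2))
        return float(g.sum()), float(np.sum(-d / sigma**2 * g))

    s = float(s0)
    times, ss, vs = [], [], []
    eta = rng.standard_normal(n_steps)
    for step in range(n_steps):
        if W0 > 0 and step % stride == 0:
            v_here, _ = bias_and_grad(s)
            centers.append(s)
            heights.append(W0 * np.exp(-v_here / kBdT))
            c_arr = np.asarray(centers)
            h_arr = np.asarray(heights)
        v, dv = bias_and_grad(s)
        force = -(float(potential.dU(s)) + dv)
        s = s + force * dt / friction + noise_scale * eta[step]
        if (step + 1) % save_stride == 0:
            v_now, _ = bias_and_grad(s)
            times.append((step + 1) * dt)
            ss.append(s)
            vs.append(v_now)
    return WTMTDResult(
        times=np.asarray(times), s=np.asarray(ss), bias=np.asarray(vs),
        centers=c_arr, heights=h_arr, sigma=sigma, gamma=gamma,
    )


def well_free_energy_difference(
    res: WTMTDResult,
    T: float = 298.0,
    lim: float = 2.5,
    n_grid: int = 501,
) -> float:
    """F(right well) - F(left well) read from the converged bias, kJ mol^-1.

    Integrates exp(-G(s)/kBT) over each half-line with G(s) from
    :meth:`WTMTDResult.free_energy_profile`.
    """
    kBT = KB_KJ_MOL * T
    grid = np.linspace(-lim, lim, n_grid)
    g = res.free_energy_profile(grid)
    w = np.exp(-(g - g.min()) / kBT)
    return float(-kBT * np.log(w[grid > 0].sum() / w[grid < 0].sum()))


def unbiased_langevin(
    potential: DoubleWell,
    n_walkers: int = 64,
    n_steps: int = 20_000,
    T: float = 298.0,
    dt: float = 0.005,
    friction: float = 1.0,
    burn_in: int = 2_000,
    seed: int = 0,
) -> np.ndarray:
    """Reference sampler: (n_walkers, n_steps - burn_in) positions.

    Walkers start alternately in each well so the estimate is not
    biased by initialisation.
    """
    rng = np.random.default_rng(seed)
    s = np.where(np.arange(n_walkers) % 2 == 0, -1.0, 1.0).astype(float)
    noise_scale = np.sqrt(2 * KB_KJ_MOL * T * dt / friction)
    out = np.empty((n_walkers, n_steps - burn_in))
    for step in range(n_steps):
        s += -potential.dU(s) * dt / friction \
            + noise_scale * rng.standard_normal(n_walkers)
        if step >= burn_in:
            out[:, step - burn_in] = s
    return out


# ---------------------------------------------------------------------------
# geometric demo solution
# ---------------------------------------------------------------------------

def gen_solution_ensemble(
    n_waters: int = 40,
    n_frames: int = 20,
    T: float = 298.0,
    k: float = 40.0,
    seed: int = 0,
    box: float = 24.0,
) -> tuple[FrameEnsemble, Topology]:
    """A small solvated scene: two 3-residue proteins, one 3-site
    polyanion, two cations and a grid of 3-site waters.

    Atoms jitter harmonically (spring ``k``) about their sites with
    consistent forces and per-atom energies, so the same ensemble
    exercises shells, hydrogen bonds, classification, contacts,
    energies and covariances.  Not a model of real water structure.
    """
    rng = np.random.default_rng(seed)
    kBT = KB_KJ_MOL * T

    element, name, mass, charge = [], [], [], []
    ua_id, monomer_id, molecule_id = [], [], []
    bonds: list[tuple[int, int]] = []
    monomer_class: dict[int, str] = {}
    species: dict[int, str] = {}
    formal_charge: dict[int, float] = {}
    residue_name: dict[int, str] = {}
    sites: list[np.ndarray] = []
    counters = {"ua": 0, "mon": 0, "mol": 0}

    def add_atom(el, nm, m_, q, ua, mon, mol, site):
        element.append(el); name.append(nm); mass.append(m_); charge.append(q)
        ua_id.append(ua); monomer_id.append(mon); molecule_id.append(mol)
        sites.append(np.asarray(site, dtype=float))
        return len(element) - 1

    def add_protein(origin, mol_q):
        mol = counters["mol"]; counters["mol"] += 1
        species[mol] = "protein"; formal_charge[mol] = mol_q
        classes = ["basic", "acidic", "non-polar"]
        prev = None
        for r, cls in enumerate(classes):
            mon = counters["mon"]; counters["mon"] += 1
            monomer_class[mon] = cls
            residue_name[mon] = {"basic": "ARG", "acidic": "ASP",
                                 "non-polar": "ALA"}[cls]
            ua = counters["ua"]; counters["ua"] += 1
            q = {"basic": 0.6, "acidic": -0.6, "non-polar": 0.0}[cls]
            a = add_atom("N" if cls == "basic" else "C", "CA", 13.0, q,
                         ua, mon, mol, origin + np.array([1.6 * r, 0, 0]))
            if prev is not None:
                bonds.append((prev, a))
            prev = a

    def add_polyanion(origin):
        mol = counters["mol"]; counters["mol"] += 1
        species[mol] = "polyanion"; formal_charge[mol] = -3.0
        mon = counters["mon"]; counters["mon"] += 1
        monomer_class[mon] = "n/a"; residue_name[mon] = "PAN"
        prev = None
        for r in range(3):
            ua = counters["ua"]; counters["ua"] += 1
            a = add_atom("O", "O", 16.0, -1.0, ua, mon, mol,
                         origin + np.array([1.5 * r, 0, 0]))
            if prev is not None:
                bonds.append((prev, a))
            prev = a

    def add_ion(origin):
        mol = counters["mol"]; counters["mol"] += 1
        species[mol] = "cation"; formal_charge[mol] = 1.0
        mon = counters["mon"]; counters["mon"] += 1
        monomer_class[mon] = "n/a"; residue_name[mon] = "NA"
        ua = counters["ua"]; counters["ua"] += 1
        add_atom("Na", "NA", 23.0, 1.0, ua, mon, mol, origin)

    def add_water(origin):
        mol = counters["mol"]; counters["mol"] += 1
        species[mol] = "water"; formal_charge[mol] = 0.0
        mon = counters["mon"]; counters["mon"] += 1
        monomer_class[mon] = "n/a"; residue_name[mon] = "HOH"
        ua = counters["ua"]; counters["ua"] += 1
        o = add_atom("O", "OW", 16.0, -0.834, ua, mon, mol, origin)
        h1 = add_atom("H", "HW1", 1.0, 0.417, ua, mon, mol,
                      origin + np.array([0.76, 0.59, 0.0]))
        h2 = add_atom("H", "HW2", 1.0, 0.417, ua, mon, mol,
                      origin + np.array([-0.76, 0.59, 0.0]))
        bonds.append((o, h1)); bonds.append((o, h2))

    c = box / 2.0
    add_protein(np.array([c - 6.0, c, c]), +2.0)
    add_protein(np.array([c + 3.0, c, c]), +2.0)
    add_polyanion(np.array([c - 2.0, c + 3.0, c]))
    add_ion(np.array([c - 2.0, c + 5.5, c]))
    add_ion(np.array([c + 2.5, c + 3.5, c]))

    # waters on a jittered grid, skipping sites too close to solutes
    occupied = np.array(sites)
    grid = np.arange(2.0, box - 2.0, 3.1)
    placed = 0
    for x in grid:
        for y in grid:
            for z in grid:
                if placed >= n_waters:
                    break
                p = np.array([x, y, z])
                if occupied.size and np.min(
                        np.linalg.norm(occupied - p, axis=1)) < 2.4:
                    continue
                add_water(p)
                occupied = np.vstack([occupied, p])
                placed += 1
    if placed < n_waters:
        raise ValueError("box too small for the requested water count")

    top = Topology(
        element=np.array(element, dtype=object),
        name=np.array(name, dtype=object),
        mass=np.array(mass, dtype=float),
        charge=np.array(charge, dtype=float),
        ua_id=np.array(ua_id, dtype=int),
        monomer_id=np.array(monomer_id, dtype=int),
        molecule_id=np.array(molecule_id, dtype=int),
        bonds=np.array(bonds, dtype=int),
        monomer_class=monomer_class,
        species=species,
        formal_charge=formal_charge,
        residue_name=residue_name,
    )
    top.validate()

    n = top.n_atoms
    site_arr = np.array(sites)
    dx = rng.normal(0.0, np.sqrt(kBT / k), size=(n_frames, n, 3))
    positions = site_arr[None] + dx
    forces = -k * dx
    pe = 0.5 * k * np.sum(dx**2, axis=2)
    ke = _maxwell_ke(rng, kBT, (n_frames, n))
    ens = FrameEnsemble(
        times=np.arange(n_frames, dtype=float),
        box=np.full((n_frames, 3), float(box)),
        positions=positions,
        forces=forces,
        pe=pe,
        ke=ke,
    )
    ens.validate()
    return ens, top


def ion_set_topology(formal_charges, role: str = "polyanion") -> Topology:
    """Monatomic stand-ins for an excipient set with given formal charges."""
    top = _monatomic_topology(
        len(formal_charges), 30.97, -1.0, role, element="P"
    )
    top.formal_charge = {i: float(q) for i, q in enumerate(formal_charges)}
    return top
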
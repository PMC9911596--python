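"""Deterministic synthetic inputs: toy structures, streams and spectra.

Everything here is generated programmatically — analytic cylinder channels
with closed-form pore radii, ideal poly-Ala helices, minimal hand-sized PDB
files, short photon streams and Lorentzian spectra — so the test suite and
the demo pipeline run without any instrument or database files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .burst import CorrectionParams
from .nmr import Spectrum31P, synth_spectrum, write_spectrum
from .photon_sim import SimConfig, SpeciesSpec, simulate_stream, write_photon_table
from .structgeom import DEFAULT_VDW, VDW_RADII, Structure

__all__ = [
    "make_structure",
    "make_cylinder",
    "make_helix",
    "write_structure_pdb",
    "toy_pdb_text",
    "demo_sim_config",
    "demo_spectrum",
    "make_fixtures",
]


def make_structure(coords, element: str = "C", chain: str = "A",
                   res_name: str = "CYL", atom_name: str = "X",
                   res_start: int = 1) -> Structure:
    """Wrap raw coordinates as a single-chain Structure, one atom per residue."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    el = element.upper()
    return Structure(
        coords=coords,
        elements=np.full(n, el),
        vdw=np.full(n, VDW_RADII.get(el, DEFAULT_VDW)),
        atom_names=np.full(n, atom_name),
        chain_ids=np.full(n, chain),
        res_seq=np.arange(res_start, res_start + n),
        res_names=np.full(n, res_name),
        het=np.zeros(n, dtype=bool),
        name="synthetic",
    )


def merge_structures(parts) -> Structure:
    """Concatenate several structures into one multi-chain model."""
    return Structure(
        coords=np.vstack([p.coords for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        vdw=np.concatenate([p.vdw for p in parts]),
        atom_names=np.concatenate([p.atom_names for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        res_seq=np.concatenate([p.res_seq for p in parts]),
        res_names=np.concatenate([p.res_names for p in parts]),
        het=np.concatenate([p.het for p in parts]),
        name="synthetic-merge",
    )


def make_cylinder(
    ring_radius: float = 8.0,
    z_min: float = 0.0,
    z_max: float = 40.0,
    n_per_ring: int = 36,
    ring_step: float = 1.5,
    element: str = "C",
    flare_rate: float = 0.0,
    flare_extent: float = 0.0,
) -> Structure:
    """Atoms on rings forming a cylinder channel with closed-form pore radius.

    With element C (vdW 1.7 Å) and ring radius 8 the inscribed pore radius is
    exactly 8 − 1.7 = 6.3 Å everywhere inside.  ``flare_rate`` > 0 appends
    mouth rings beyond both ends whose radius grows linearly with axial
    distance, emulating vestibules that open the channel.
    """
    zs = list(np.arange(z_min, z_max + 0.5 * ring_step, ring_step))
    radii = [ring_radius] * len(zs)
    if flare_rate > 0 and flare_extent > 0:
        for dz in np.arange(ring_step, flare_extent + 0.5 * ring_step, ring_step):
            zs += [z_min - dz, z_max + dz]
            radii += [ring_radius + flare_rate * dz] * 2
    theta = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
    pts = []
    for z, r in zip(zs, radii):
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                    np.full(n_per_ring, z)]))
    return make_structure(np.vstack(pts), element=element)


def make_helix(
    n_res: int = 30,
    rise: float = 1.5,
    helix_radius: float = 2.3,
    twist_deg: float = 100.0,
    direction=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    chain: str = "A",
) -> Structure:
    """Ideal poly-Ala Cα helix (rise 1.5 Å/res, 100°/res) along ``direction``."""
    t = np.arange(n_res)
    ang = np.deg2rad(twist_deg) * t
    local = np.column_stack([
        helix_radius * np.cos(ang),
        helix_radius * np.sin(ang),
        rise * t,
    ])
    ez = np.asarray(direction, dtype=float)
    ez /= np.linalg.norm(ez)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(ez @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    ex = np.cross(helper, ez)
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    coords = local @ np.vstack([ex, ey, ez]) + np.asarray(origin, dtype=float)
    st = make_structure(coords, element="C", chain=chain, res_name="ALA",
                        atom_name="CA")
    return st


def write_structure_pdb(struct: Structure, path) -> None:
    """Minimal PDB writer (coordinates to the format's 3-decimal precision)."""
    with open(path, "w") as fh:
        for i in range(struct.n_atoms):
            x, y, z = struct.coords[i]
            record = "HETATM" if struct.het[i] else "ATOM  "
            name = str(struct.atom_names[i])[:4]
            fh.write(
                f"{record}{(i + 1) % 100000:5d} {name:>4s} "
                f"{str(struct.res_names[i])[:3]:>3s} {str(struct.chain_ids[i])[:1]}"
                f"{int(struct.res_seq[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{str(struct.elements[i])[:2]:>2s}\n"
            )
        fh.write("END\n")


def toy_pdb_text() -> str:
    """A hand-written 3-atom, 1-residue PDB file."""
    return (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C\n"
        "END\n"
    )


def demo_sim_config(seed: int = 0, duration_s: float = 60.0,
                    two_species: bool = True) -> SimConfig:
    """The study conditions: activated high-FRET species at the Förster
    efficiency of the 42.6 Å modelled distance (R0 = 52 Å), plus an
    optional broad low-FRET inactive species, with LK = 0.13, Di = 0.06,
    γ = 0.47 embedded generatively."""
    from .forster import efficiency_from_distance

    e_high = efficiency_from_distance(42.6, 52.0)
    if two_species:
        species = (
            SpeciesSpec("inactive_low", true_e=0.30, fraction=0.4),
            SpeciesSpec("activated_high", true_e=e_high, fraction=0.6),
        )
    else:
        species = (SpeciesSpec("activated_high", true_e=e_high, fraction=1.0),)
    return SimConfig(
        species=species,
        duration_s=duration_s,
        burst_rate=20.0,
        background_dd=500.0,
        background_da=500.0,
        background_aa=500.0,
        correction=CorrectionParams(),
        seed=seed,
    )


def demo_spectrum(polyp_mm: float = 10.0, seed: int = 0,
                  noise_sd: float = 0.0) -> Spectrum31P:
    """Synthetic in-cell spectrum: MDP reference plus polyP terminal/central
    peaks carrying the requested phosphate concentration (mM)."""
    # reference: 3.3 mM x 2 nuclei -> area 6.6 in concentration units
    ref_area = 3.3 * 2
    peaks = [
        (20.58, ref_area, 0.15),
        (-7.0, polyp_mm * 0.2, 0.15),   # terminal residues
        (-22.0, polyp_mm * 0.8, 0.15),  # central residues
    ]
    return synth_spectrum(peaks, noise_sd=noise_sd, seed=seed)


def make_fixtures(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the small deterministic fixture set used by tests and demos.

    Produces a toy 3-atom PDB, the analytic cylinder channel, an ideal TM
    helix, a short two-species photon stream, a flat simulation config and a
    synthetic ³¹P spectrum.  Returns {fixture name: path}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    toy = out / "toy.pdb"
    toy.write_text(toy_pdb_text())
    paths["toy_pdb"] = str(toy)

    cyl = out / "cylinder.pdb"
    write_structure_pdb(
        make_cylinder(flare_rate=10.0, flare_extent=6.0), cyl
    )
    paths["cylinder_pdb"] = str(cyl)

    helix = out / "helix.pdb"
    write_structure_pdb(make_helix(n_res=30), helix)
    paths["helix_pdb"] = str(helix)

    cfg = demo_sim_config(seed=seed, duration_s=10.0)
    stream = out / "photons.tsv"
    write_photon_table(simulate_stream(cfg), stream)
    paths["photon_tsv"] = str(stream)

    cfg_file = out / "sim_config.txt"
    lines = [
        f"duration_s = {cfg.duration_s}",
        f"burst_rate = {cfg.burst_rate}",
        f"background_dd = {cfg.background_dd}",
        f"background_da = {cfg.background_da}",
        f"background_aa = {cfg.background_aa}",
        f"lk = {cfg.correction.lk}",
        f"di = {cfg.correction.di}",
        f"gamma = {cfg.correction.gamma}",
        f"r0 = {cfg.correction.r0}",
        f"seed = {cfg.seed}",
    ]
    for i, sp in enumerate(cfg.species, 1):
        lines += [
            f"species.{i}.name = {sp.name}",
            f"species.{i}.true_e = {sp.true_e}",
            f"species.{i}.fraction = {sp.fraction}",
        ]
    cfg_file.write_text("\n".join(lines) + "\n")
    paths["sim_config"] = str(cfg_file)

    spec_file = out / "spectrum.tsv"
    write_spectrum(demo_spectrum(seed=seed, noise_sd=0.005), spec_file)
    paths["spectrum_tsv"] = str(spec_file)

    return paths
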
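"""Self-contained fixture generation for tests, demos and reproduction runs.

``generate_fixture`` writes small files on demand: short synthetic MD/PIMD
trajectories on the analytic bridge potentials, a deliberately malformed
trajectory for error-path checks, and the two descriptor tables
(QTAIM bond-critical-point properties of the benzamide/benzoic-acid dimers
and their SAPT2+/aDZ interaction-energy decompositions) transcribed from
the published crystallographic study these analyses accompany.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigurationError
from .model_systems import (
    ModelPotential,
    PathSettings,
    SimulationSettings,
    simulate_md,
    simulate_pimd,
)
from .trajectory_io import write_bead_trajectory, write_xyz

__all__ = ["generate_fixture", "TABLE2_QTAIM_CSV", "TABLE3_SAPT_CSV"]

# QTAIM properties at bond critical points (atomic units; E1 in kcal/mol).
# Systems: (D1)/(D2) experimental/optimized 2,6-difluorobenzamide dimer,
# (E1)/(E2) experimental/optimized 4-hydroxybenzoic acid dimer.
# "-" marks shared-shell bonds where the Espinosa correlation does not apply.
TABLE2_QTAIM_CSV = """\
system,label,rho,V_BCP,laplacian,H_BCP,E1
D1,ND-H...OA,0.0183,-0.0124,0.0790,0.0037,3.9029
D1,F...N,0.0110,-0.0089,0.0601,0.0031,2.7829
D1,ND-H,0.4652,-1.0418,-3.5875,-0.9694,-
D1,C=OA,0.4046,-1.3240,-0.5213,-0.7272,-
E1,OD-H...OA,0.0384,-0.0381,0.1349,-0.0022,11.9557
E1,OD-H,0.4178,-0.9894,-3.3106,-0.9085,-
E1,C=OA,0.4069,-1.3567,-0.4383,-0.7331,-
D2,ND-H...OA,0.0302,-0.0254,0.1031,0.0002,7.9586
D2,ND-H,0.3229,-0.5649,-1.8740,-0.5167,-
D2,C=OA,0.4074,-1.3773,-0.4297,-0.7423,-
E2,OD-H...OA,0.0522,-0.0554,0.1237,-0.0122,17.3707
E2,OD-H,0.3092,-0.6476,-2.0757,-0.5833,-
E2,C=OA,0.4058,-1.3759,-0.4073,-0.7388,-
"""

# SAPT2+/aDZ interaction-energy components, kcal/mol.
TABLE3_SAPT_CSV = """\
label,E_elst,E_exch,E_ind,E_disp,E_total
D1,-15.730,13.619,-4.656,-5.380,-12.146
E1,-27.448,33.520,-12.021,-8.788,-14.736
D2,-24.472,27.813,-10.886,-8.037,-15.582
E2,-35.921,46.756,-21.032,-10.774,-20.970
"""

_MALFORMED_TRAJECTORY = """\
1  0.0 0.0 0.0  0.0 0.0 0.0
1  1.0 0.0 0.0  0.0 0.0 0.0
2  0.0 0.0 0.0  0.0 0.0 0.0
2  1.1 0.0 0.0  0.0 0.0 0.0  0.5
"""

FIXTURE_KINDS = (
    "harmonic_md",
    "double_well_md",
    "double_well_pimd",
    "malformed_trajectory",
    "table2_csv",
    "table3_csv",
)


def generate_fixture(kind: str, seed: int = 0, outdir=".") -> list[Path]:
    """Write the named fixture into ``outdir``; returns the created paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "table2_csv":
        path = outdir / "qtaim_table.csv"
        path.write_text(TABLE2_QTAIM_CSV)
        return [path]
    if kind == "table3_csv":
        path = outdir / "sapt_table.csv"
        path.write_text(TABLE3_SAPT_CSV)
        return [path]
    if kind == "malformed_trajectory":
        path = outdir / "malformed.trj"
        path.write_text(_MALFORMED_TRAJECTORY)
        return [path]
    if kind == "harmonic_md":
        model = ModelPotential(kind="harmonic")
        settings = SimulationSettings(n_steps=2000, n_equil=200, seed=seed)
        traj = simulate_md(model, settings)
        path = outdir / "harmonic_md.xyz"
        write_xyz(traj, path)
        return [path]
    if kind == "double_well_md":
        model = ModelPotential(kind="double_well")
        settings = SimulationSettings(n_steps=2000, n_equil=200, seed=seed)
        traj = simulate_md(model, settings)
        path = outdir / "double_well_md.xyz"
        write_xyz(traj, path)
        return [path]
    if kind == "double_well_pimd":
        model = ModelPotential(kind="double_well")
        settings = SimulationSettings(n_steps=500, n_equil=100, seed=seed)
        btraj = simulate_pimd(model, settings, PathSettings(P=8))
        return write_bead_trajectory(btraj, outdir / "double_well_pimd")
    raise ConfigurationError(
        f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
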
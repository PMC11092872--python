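"""Run configuration, trajectory/observable output and the run dispatcher.

Configs are flat YAML key-value files that round-trip losslessly through
:class:`RunConfig`.  Every output file carries the seed and a hash of the
config in a comment header.  Trajectories are XYZ-style frames for the
polymer (the element column encodes the monomer type) followed by a
sparse block listing bulk-occupied sites per species; frames are
self-delimiting and re-parsable by the analyze mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .hamiltonian import ModelParams
from .lattice import LatticeGeometry
from .meanfield import MeanFieldParams, scan_transition
from .observables import TrajectoryFrame
from .polymer import SegmentSpec


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: model, schedule, mode, seed."""

    mode: str = "minimal"          # full | minimal | meanfield | analyze | enumerate
    out_dir: str = "prewet_out"
    seed: int = 0
    # lattice model
    L: int = 16
    mu_p: float = 0.0
    v_p: float = 0.0
    mu_b: float = 0.0
    N_b: int = 20
    j_bulk: float = 0.0
    j_nn: float = 0.0
    j_int: Union[float, Dict[int, float]] = 0.0
    N_max: int = 120
    delta: int = 12
    p_kink: float = 0.2
    segments: Optional[List[List[int]]] = None   # [[type, count], ...]
    n_reservoir: int = 1000
    # schedule
    n_sweeps: int = 20000
    n_equil: int = 5000
    cadence: int = 10
    pre_equil_sweeps: int = 0
    shell_radius: int = 0
    write_trajectory: bool = True
    # mean-field (v_p and mu_b above are shared with the lattice model)
    mf_N_p: float = 1.0e6
    mf_a: float = 1.0
    mf_t_b: float = 1.0
    mf_u: float = 6.0
    mf_h: float = 0.0
    scan_axis: str = "v_p"
    scan_start: float = -1.0
    scan_stop: float = 1.0
    scan_step: float = 0.01
    # enumerate mode
    enum_kind: str = "walks"       # walks | gas
    enum_dims: List[int] = field(default_factory=lambda: [3, 3, 4])
    enum_start: List[int] = field(default_factory=lambda: [0, 0, 0])
    enum_end: List[int] = field(default_factory=lambda: [2, 2, 3])
    enum_N_max: int = 10
    # analyze mode
    analyze_input: Optional[str] = None
    contact_bin_size: int = 1

    _MODES = ("full", "minimal", "meanfield", "analyze", "enumerate")

    def validate(self) -> None:
        bad = []
        if self.mode not in self._MODES:
            bad.append(f"mode={self.mode!r}")
        for key in ("n_sweeps", "cadence", "L", "N_b", "N_max"):
            if getattr(self, key) <= 0:
                bad.append(f"{key}={getattr(self, key)}")
        if self.n_equil < 0 or self.pre_equil_sweeps < 0:
            bad.append(f"n_equil={self.n_equil}")
        if not 0 <= self.p_kink < 1:
            bad.append(f"p_kink={self.p_kink}")
        if self.scan_step <= 0:
            bad.append(f"scan_step={self.scan_step}")
        if bad:
            raise ConfigError("invalid config values: " + ", ".join(bad))

    # -- conversions --------------------------------------------------------

    def model_params(self) -> ModelParams:
        j_int = self.j_int
        if isinstance(j_int, dict):
            j_int = {int(k): float(v) for k, v in j_int.items()}
        return ModelParams(L=self.L, mu_p=self.mu_p, v_p=self.v_p,
                           mu_b=self.mu_b, N_b=self.N_b, j_bulk=self.j_bulk,
                           j_nn=self.j_nn, j_int=j_int, N_max=self.N_max,
                           delta=self.delta, p_kink=self.p_kink,
                           seed=self.seed)

    def meanfield_params(self) -> MeanFieldParams:
        return MeanFieldParams(N_p=self.mf_N_p, a=self.mf_a, v_p=self.v_p,
                               t_b=self.mf_t_b, u=self.mf_u, mu_b=self.mu_b,
                               h=self.mf_h)

    def segment_spec(self) -> Optional[SegmentSpec]:
        if not self.segments:
            return None
        return SegmentSpec(blocks=tuple((int(t), int(c))
                                        for t, c in self.segments),
                           delta=self.delta)

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError("unknown config keys: " + ", ".join(sorted(unknown)))
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# Trajectory format
# ---------------------------------------------------------------------------

def write_frame(chain, state, stream: TextIO, sweep: int = 0) -> None:
    """Append one self-delimiting frame: XYZ polymer block + sparse bulk."""
    sites = chain.sites
    stream.write(f"{len(sites)}\n")
    stream.write(f"sweep={sweep}\n")
    for i, s in enumerate(sites):
        t = chain.type_of(i)
        stream.write(f"T{t} {s[0]} {s[1]} {s[2]}\n")
    s1 = sorted(state.species1_sites())
    s2 = sorted(state.fields.s2) if state.gas is None else []
    stream.write(f"BULK1 {len(s1)}\n")
    for s in s1:
        stream.write(f"{s[0]} {s[1]} {s[2]}\n")
    stream.write(f"BULK2 {len(s2)}\n")
    for s in s2:
        stream.write(f"{s[0]} {s[1]} {s[2]}\n")
    stream.write("ENDFRAME\n")


def read_frames(path: Union[str, Path]) -> List[TrajectoryFrame]:
    """Parse a trajectory written by :func:`write_frame`."""
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()
                 and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        natoms = int(lines[i])
        i += 2  # skip comment line
        sites, types = [], []
        for _ in range(natoms):
            parts = lines[i].split()
            types.append(int(parts[0].lstrip("T")))
            sites.append((int(parts[1]), int(parts[2]), int(parts[3])))
            i += 1
        s1, s2 = set(), set()
        for target in (s1, s2):
            n = int(lines[i].split()[1])
            i += 1
            for _ in range(n):
                p = lines[i].split()
                target.add((int(p[0]), int(p[1]), int(p[2])))
                i += 1
        assert lines[i] == "ENDFRAME", f"malformed frame near line {i}"
        i += 1
        frames.append(TrajectoryFrame(sites=sites, types=types, s1=s1, s2=s2))
    return frames


# ---------------------------------------------------------------------------
# Tabular output with provenance headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_matrix(mat: np.ndarray, path: Path, config: RunConfig,
                 label: str) -> None:
    header = (f"{label} shape={mat.shape[0]}x{mat.shape[1]} "
              f"seed={config.seed} config={config.config_hash()}")
    np.savetxt(path, mat, header=header)


# ---------------------------------------------------------------------------
# Run dispatcher
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> Dict[str, Path]:
    """Execute the configured mode; returns the files written.

    Identical seed + config produce identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    log_lines = [f"prewet run mode={config.mode} seed={config.seed} "
                 f"config={config.config_hash()}"]
    t0 = time.time()

    (out / "config.yaml").write_text(
        f"# config={config.config_hash()}\n" + config.to_yaml())
    written["config"] = out / "config.yaml"

    if config.mode == "minimal":
        from .simulate import run_minimal
        res = run_minimal(config.model_params(), n_sweeps=config.n_sweeps,
                          n_equil=config.n_equil, cadence=config.cadence,
                          seed=config.seed)
        write_table(res.table, out / "observables.csv", config)
        written["observables"] = out / "observables.csv"
        if config.write_trajectory:
            from .system import SystemState
            state = SystemState(geometry=LatticeGeometry.cubic(config.L),
                                chain=res.final_chain, gas=res.final_gas)
            with open(out / "final_frame.xyz", "w") as fh:
                fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
                write_frame(res.final_chain, state, fh,
                            sweep=config.n_sweeps)
            written["final_frame"] = out / "final_frame.xyz"
        log_lines += [f"acceptance {k}={v:.4f}"
                      for k, v in res.acceptance.items()]

    elif config.mode == "full":
        from .simulate import run_full
        res = run_full(config.model_params(), n_sweeps=config.n_sweeps,
                       n_equil=config.n_equil, cadence=config.cadence,
                       seed=config.seed, n_reservoir=config.n_reservoir,
                       segments=config.segment_spec(),
                       pre_equil_sweeps=config.pre_equil_sweeps,
                       shell_radius=config.shell_radius,
                       keep_frames=config.write_trajectory)
        write_table(res.table, out / "observables.csv", config)
        written["observables"] = out / "observables.csv"
        if config.write_trajectory:
            with open(out / "trajectory.xyz", "w") as fh:
                fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
                for fr, sweep in zip(res.frames, res.table["sweep"]):
                    chain_view = _frame_chain(fr)
                    state_view = _frame_state(fr, config.L)
                    write_frame(chain_view, state_view, fh, sweep=int(sweep))
            written["trajectory"] = out / "trajectory.xyz"
        log_lines += [f"acceptance {k}={v:.4f}"
                      for k, v in res.acceptance.items()]

    elif config.mode == "meanfield":
        values = np.arange(config.scan_start,
                           config.scan_stop + config.scan_step / 2,
                           config.scan_step)
        result = scan_transition(config.meanfield_params(), config.scan_axis,
                                 values)
        write_table(result.table, out / "scan.csv", config)
        written["scan"] = out / "scan.csv"
        log_lines.append(
            f"transition found={result.found} location={result.location} "
            f"order={result.order}")

    elif config.mode == "enumerate":
        from .oracle import enumerate_lattice_gas, enumerate_pinned_walks
        geometry = LatticeGeometry(tuple(config.enum_dims))
        params = config.model_params()
        if config.enum_kind == "walks":
            start = tuple(config.enum_start)
            end = tuple(config.enum_end)
            r = enumerate_pinned_walks(
                geometry, start, end, config.enum_N_max, params,
                displacement=geometry.displacement(start, end))
        else:
            r = enumerate_lattice_gas(geometry, params)
        row = {"Z": r.Z, "n_states": r.n_states}
        row.update(r.means)
        write_table(pd.DataFrame([row]), out / "enumeration.csv", config)
        written["enumeration"] = out / "enumeration.csv"

    elif config.mode == "analyze":
        from .observables import (contact_map, contour_occupancy,
                                  occupancy_profile)
        src = config.analyze_input or str(out / "trajectory.xyz")
        frames = read_frames(src)
        geometry = LatticeGeometry.cubic(config.L)
        write_table(occupancy_profile(frames), out / "occupancy_by_type.csv",
                    config)
        write_table(contour_occupancy(frames), out / "contour_occupancy.csv",
                    config)
        cm = contact_map(frames, geometry, bin_size=config.contact_bin_size)
        write_matrix(cm, out / "contact_map.txt", config, "contact_map")
        written.update({"occupancy_by_type": out / "occupancy_by_type.csv",
                        "contour_occupancy": out / "contour_occupancy.csv",
                        "contact_map": out / "contact_map.txt"})

    log_lines.append(f"elapsed_s={time.time() - t0:.2f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    written["log"] = out / "run.log"
    return written


def _frame_chain(frame: TrajectoryFrame):
    from .polymer import PolymerChain
    return PolymerChain(sites=frame.sites, types=frame.types)


def _frame_state(frame: TrajectoryFrame, L: int):
    from .system import SystemState
    state = SystemState(geometry=LatticeGeometry.cubic(L))
    state.fields.s1 = frame.s1
    state.fields.s2 = frame.s2
    return state
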
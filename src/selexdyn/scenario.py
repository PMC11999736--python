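"""Scenario configuration files, trajectory TSV I/O and fixture generation.

A scenario is a TOML file with three blocks::

    [pool]
    Q = 0.2
    kback = 0.001

    [[pool.catalysts]]
    label = "seq1"
    A = 0.55
    k = 1.0
    p0 = 1e-14
    # optional per-species cofactor behaviour for counter-selection:
    # mode = "dependent"        # constitutive | dependent | leaky
    # leak_factor = 0.5

    [pool.artefact]
    Rart = 0.02
    p0 = 1e-14

    [schedule]                  # either an explicit list ...
    # taus = [5.0, 5.0, 1.0]
    tau0 = 5.0                  # ... or the stepped shorthand
    factor = 5.0
    first_decay_round = 6

    [counter_schedule]          # optional; defaults to [schedule]
    tau0 = 5.0
    factor = 1.0
    first_decay_round = 1

    [run]
    rounds = 20
    seed = 0

Unknown keys anywhere are rejected with a message listing them, and
initial frequencies that leave nothing for the background are rejected.
Trajectories are written as TSV with ``#`` header comments carrying the
library version, seed and a hash of the configuration; floats use 17
significant digits so a written trajectory reads back bit-exactly.
"""

from __future__ import annotations

import hashlib
import io
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .kinetics import ReactionParams
from .selection import CofactorPool, CofactorSpecies, SpeciesPool, TauSchedule, Trajectory
from .structure import format_structure

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "write_trajectory",
    "read_trajectory",
    "make_fixtures",
]

_POOL_KEYS = {"Q", "kback", "catalysts", "artefact"}
_CATALYST_KEYS = {"label", "A", "k", "p0", "mode", "leak_factor"}
_ARTEFACT_KEYS = {"Rart", "p0"}
_SCHEDULE_KEYS = {"taus", "tau0", "factor", "first_decay_round"}
_RUN_KEYS = {"rounds", "seed"}
_TOP_KEYS = {"pool", "schedule", "counter_schedule", "run"}


@dataclass
class ScenarioConfig:
    """A validated selection scenario.

    Exactly one of ``pool`` (plain selection) and ``cofactor_pool``
    (counter-selection, triggered by any catalyst declaring a
    cofactor ``mode``) is set.
    """

    pool: SpeciesPool | None
    cofactor_pool: CofactorPool | None
    schedule: TauSchedule
    counter_schedule: TauSchedule | None
    rounds: int
    seed: int | None
    source_hash: str

    @property
    def is_counter_selection(self) -> bool:
        return self.cofactor_pool is not None


def _reject_unknown(block: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {', '.join(unknown)}")


def _parse_schedule(block: dict, where: str) -> TauSchedule:
    _reject_unknown(block, _SCHEDULE_KEYS, where)
    if "taus" in block:
        if {"tau0", "factor", "first_decay_round"} & set(block):
            raise ValueError(f"{where}: give either taus or the stepped shorthand, not both")
        return TauSchedule(taus=tuple(block["taus"]))
    try:
        return TauSchedule.stepped(block["tau0"], block["factor"], block["first_decay_round"])
    except KeyError as exc:
        raise ValueError(f"{where}: stepped schedule needs {exc.args[0]}") from None


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario TOML file."""
    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode())
    _reject_unknown(data, _TOP_KEYS, "scenario")
    if "pool" not in data:
        raise ValueError("scenario must declare a [pool] block")
    pool_block = data["pool"]
    _reject_unknown(pool_block, _POOL_KEYS, "[pool]")
    catalysts = pool_block.get("catalysts", [])
    if not catalysts:
        raise ValueError("[pool] must list at least one [[pool.catalysts]] entry")
    for entry in catalysts:
        _reject_unknown(entry, _CATALYST_KEYS, f"catalyst {entry.get('label', '?')!r}")
        for key in ("label", "A", "k", "p0"):
            if key not in entry:
                raise ValueError(f"catalyst entry missing {key!r}")
    Q = float(pool_block.get("Q", 0.2))
    kback = float(pool_block.get("kback", 0.001))
    p0 = [float(e["p0"]) for e in catalysts]
    if sum(p0) > 1.0:
        raise ValueError(f"catalyst frequencies sum to {sum(p0)!r} > 1; cannot normalize")

    counter = any("mode" in e for e in catalysts)
    pool: SpeciesPool | None = None
    cof_pool: CofactorPool | None = None
    if counter:
        if "artefact" in pool_block:
            raise ValueError("artefact block is not supported in a counter-selection scenario")
        species = [
            CofactorSpecies(
                e["label"],
                A=float(e["A"]),
                k=float(e["k"]),
                mode=e.get("mode", "constitutive"),
                leak_factor=float(e.get("leak_factor", 0.5)),
            )
            for e in catalysts
        ]
        cof_pool = CofactorPool(species=species, p0=p0, Q=Q, kback=kback)
    else:
        art = pool_block.get("artefact")
        if art is not None:
            _reject_unknown(art, _ARTEFACT_KEYS, "[pool.artefact]")
            if "Rart" not in art:
                raise ValueError("[pool.artefact] needs Rart")
        pool = SpeciesPool(
            catalysts=[
                ReactionParams(e["label"], float(e["A"]), float(e["k"])) for e in catalysts
            ],
            p0=p0,
            Q=Q,
            kback=kback,
            artefact_Rart=float(art["Rart"]) if art else None,
            artefact_p0=float(art.get("p0", 0.0)) if art else 0.0,
        )

    if "schedule" not in data:
        raise ValueError("scenario must declare a [schedule] block")
    schedule = _parse_schedule(data["schedule"], "[schedule]")
    counter_schedule = None
    if "counter_schedule" in data:
        if not counter:
            raise ValueError("[counter_schedule] given but no catalyst declares a cofactor mode")
        counter_schedule = _parse_schedule(data["counter_schedule"], "[counter_schedule]")

    run = data.get("run", {})
    _reject_unknown(run, _RUN_KEYS, "[run]")
    rounds = int(run.get("rounds", 20))
    if rounds < 1:
        raise ValueError("run.rounds must be >= 1")
    seed = run.get("seed")
    return ScenarioConfig(
        pool=pool,
        cofactor_pool=cof_pool,
        schedule=schedule,
        counter_schedule=counter_schedule,
        rounds=rounds,
        seed=None if seed is None else int(seed),
        source_hash=hashlib.sha256(raw).hexdigest()[:16],
    )


def _version() -> str:
    from . import __version__

    return __version__


def write_trajectory(
    trajectory: Trajectory,
    path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a trajectory as TSV with provenance header comments."""
    frame = trajectory.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# selexdyn {_version()}\n")
        fh.write(f"# seed {'none' if seed is None else seed}\n")
        fh.write(f"# config {config_hash or 'none'}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Read a TSV trajectory back into a Trajectory (inverse of write_trajectory)."""
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    labels = list(dict.fromkeys(frame["species"]))
    roles = [frame.loc[frame["species"] == lab, "role"].iloc[0] for lab in labels]
    rounds = sorted(frame["round"].unique())
    freqs = np.array(
        [
            [
                float(frame[(frame["round"] == n) & (frame["species"] == lab)]["frequency"].iloc[0])
                for lab in labels
            ]
            for n in rounds
        ]
    )
    by_round = frame.drop_duplicates("round").set_index("round")
    taus = by_round.loc[rounds[1:], "tau"].to_numpy(dtype=float)
    rbar = by_round.loc[rounds[1:], "mean_recovery"].to_numpy(dtype=float)
    return Trajectory(labels=labels, roles=roles, taus=taus, freqs=freqs, mean_recovery=rbar)


_EXAMPLE_SCENARIO = """\
# Four-catalyst example pool; stepped stringency schedule.
[pool]
Q = 0.2
kback = 0.001
{artefact}
[[pool.catalysts]]
label = "seq1"
A = 0.55
k = 1.0
p0 = 1e-14

[[pool.catalysts]]
label = "seq2"
A = 0.5
k = 0.8
p0 = 1e-14

[[pool.catalysts]]
label = "seq3"
A = 0.7
k = 0.6
p0 = 1e-14

[[pool.catalysts]]
label = "seq4"
A = 0.5
k = 0.5
p0 = 1e-14

[schedule]
tau0 = 5.0
factor = {factor}
first_decay_round = {first_decay_round}

[run]
rounds = 20
seed = {seed}
"""

_COUNTER_SCENARIO = """\
# Cofactor-dependence trio for counter-selection.
[pool]
Q = 0.2
kback = 0.001

[[pool.catalysts]]
label = "seq1"
A = 0.5
k = 1.0
p0 = 1e-14
mode = "constitutive"

[[pool.catalysts]]
label = "seq2"
A = 0.5
k = 0.8
p0 = 1e-14
mode = "dependent"

[[pool.catalysts]]
label = "seq3"
A = 0.5
k = 0.8
p0 = 1e-14
mode = "leaky"
leak_factor = 0.5

[schedule]
tau0 = 5.0
factor = 1.0
first_decay_round = 1

[counter_schedule]
tau0 = 5.0
factor = 1.0
first_decay_round = 1

[run]
rounds = 20
seed = {seed}
"""


def make_fixtures(outdir, seed: int = 0) -> list[Path]:
    """Write the deterministic fixture files used by the documentation and tests.

    Emits the constant-tau and stepped-tau scenarios (with and without
    an artefact), the counter-selection scenario, and the structure
    fixture files.  Identical seeds produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        paths.append(p)

    _write(
        "constant_tau.toml",
        _EXAMPLE_SCENARIO.format(artefact="", factor=1.0, first_decay_round=1, seed=seed),
    )
    _write(
        "stepped_tau.toml",
        _EXAMPLE_SCENARIO.format(artefact="", factor=5.0, first_decay_round=6, seed=seed),
    )
    artefact_block = "[pool.artefact]\nRart = 0.02\np0 = 1e-14\n"
    _write(
        "stepped_tau_artefact.toml",
        _EXAMPLE_SCENARIO.format(
            artefact=artefact_block, factor=5.0, first_decay_round=6, seed=seed
        ),
    )
    _write("counter_selection.toml", _COUNTER_SCENARIO.format(seed=seed))
    for builder in (
        presets.hammerhead_structure,
        presets.twister_structure,
        presets.triphosphorylation_structure,
        presets.toy_structure,
        presets.toy_two_module_structure,
    ):
        sc = builder()
        _write(sc.name.replace("-", "_") + ".structure", format_structure(sc))
    return paths
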
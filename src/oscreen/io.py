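"""Run configuration, result schemas and the in-silico NF-kB scenario.

A single YAML/JSON file configures enumeration, the sampler ranges, the
noise magnitudes, scale factors for reduced runs and seeds.  Every
output artifact embeds the configuration hash and master seed so that
deterministic stages are reproducible byte-for-byte and stochastic
stages are statistically reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import (
    ParameterSet,
    detect_oscillation,
    simulate_deterministic,
    state_at_b_peak,
)
from .metrics import measure_tau
from .noise import ExtrinsicNoiseConfig, IntrinsicNoiseConfig, derive_seed
from .screen import (
    REDUCED_SCALE,
    SamplerConfig,
    ScreenScale,
    run_category_screen,
)
from .topology import (
    IsolationConvention,
    SignedTopology,
    enumerate_topologies,
    save_topologies,
    topology_id,
)

log = logging.getLogger("oscreen")


@dataclass
class NfkbSweepConfig:
    """The synthetic NF-kB circuit sweep (activator-inhibitor core with a
    repressilator closed through node C at strength 1/K_CA).

    Nodes map A = IkBa (inhibitor), B = RelA (activator, positively
    autoregulated), C = the MAPK arm (Fus3, silenced by RelA via Msg5).
    ``inv_K_CA_values`` sweeps the C -| A inhibition strength upward
    from (near) zero, where the model reduces to the plain
    activator-inhibitor.
    """

    inv_K_CA_values: tuple = (1e-6, 0.05, 0.1, 0.2, 0.4)
    n_repeats: int = 100
    horizon_mult: float = 30.0
    seed: int = 0


@dataclass
class RunConfig:
    """Top-level run configuration; every block is optional in the file."""

    seed: int = 0
    outdir: str = "results"
    convention: str = "in_and_out_cross"
    categories: dict = field(
        default_factory=lambda: {
            "C1": 10, "C2": 10, "C3": 10, "C4": 10, "C5": 10, "C13": 6,
        }
    )
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scale: ScreenScale = field(default_factory=lambda: REDUCED_SCALE)
    extrinsic: ExtrinsicNoiseConfig = field(default_factory=ExtrinsicNoiseConfig)
    intrinsic: IntrinsicNoiseConfig = field(default_factory=IntrinsicNoiseConfig)
    nfkb: NfkbSweepConfig = field(default_factory=NfkbSweepConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (
            ("sampler", SamplerConfig),
            ("scale", ScreenScale),
            ("extrinsic", ExtrinsicNoiseConfig),
            ("intrinsic", IntrinsicNoiseConfig),
            ("nfkb", NfkbSweepConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for name, value in block.items():
                    if isinstance(value, list):
                        block[name] = tuple(value)
                kwargs[key] = sub(**block)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_with_provenance(payload: dict, config: RunConfig, path: Path) -> None:
    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **payload,
    }
    path.write_text(json.dumps(payload, indent=1, default=str))


# -- commands ------------------------------------------------------------------


def cmd_enumerate(config: RunConfig) -> dict:
    """Write topologies.json plus raw/post-symmetry/post-exclusion counts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        convention = IsolationConvention(config.convention)
    except ValueError:
        raise ValueError(
            f"bad convention name {config.convention!r}; options: "
            f"{[c.value for c in IsolationConvention]}"
        ) from None
    universe = enumerate_topologies(convention)
    n2 = sum(1 for t in universe if t.n_nodes == 2)
    summary = {
        "convention": convention.value,
        "raw_labeled_3node": 3**9,
        "raw_labeled_2node": 3**4,
        "canonical_2node": n2,
        "canonical_3node": len(universe) - n2,
        "combined": len(universe),
    }
    save_topologies(universe, outdir / "topologies.json")
    _write_with_provenance(summary, config, outdir / "enumeration_summary.json")
    log.info("enumerated %d topologies under %s", len(universe), convention.value)
    return summary


def cmd_screen(config: RunConfig) -> pd.DataFrame:
    """Run the two-step category screen and write all result tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_category_screen(
        config.categories,
        scale=config.scale,
        sampler=config.sampler,
        extrinsic_cfg=config.extrinsic,
        intrinsic_cfg=config.intrinsic,
        seed=config.seed,
        # checkpoints are keyed by the config hash so stale state from a
        # different configuration is never reused
        checkpoint_dir=outdir / "checkpoints" / config.config_hash(),
        progress=True,
    )
    if result.table.empty:
        log.warning("screen produced no topologies (empty category request?)")
        return result.table
    result.table.to_csv(outdir / "robustness_scores.csv", index=False)
    counts = result.table[
        ["topology_id", "category", "step1_count", "n_sets", "n_resampled"]
    ]
    counts.to_csv(outdir / "oscillatory_counts.csv", index=False)
    _write_with_provenance(
        {"reports": result.reports}, config, outdir / "category_report.json"
    )
    return result.table


# -- the NF-kB fixture and sweep ----------------------------------------------


def nfkb_topology(with_repressilator: bool = True) -> SignedTopology:
    """Circuit wiring: B -> A, A -| B, B -> B, B -| C and, when the
    repressilator arm is present, C -| A."""
    links = [
        ("B", "A", 1),
        ("A", "B", -1),
        ("B", "B", 1),
        ("B", "C", -1),
    ]
    if with_repressilator:
        links.append(("C", "A", -1))
    return SignedTopology.from_links(3, links)


def nfkb_parameters(inv_K_CA: float, base: dict | None = None) -> ParameterSet:
    """Frozen oscillatory parameter set for the circuit, with the C -| A
    binding affinity set to 1/inv_K_CA (near-zero inv_K_CA recovers the
    plain activator-inhibitor)."""
    from .screen import FIXTURE_PARAMS

    flat = dict(base or FIXTURE_PARAMS["nfkb_base"])
    flat["K_CA"] = 1.0 / max(inv_K_CA, 1e-12)
    return ParameterSet.from_flat_dict(nfkb_topology(True), flat)


def cmd_nfkb_sweep(config: RunConfig) -> pd.DataFrame:
    """Sweep 1/K_CA and record period, amplitude and tau/T under both
    noise modes (mean and SD over ``n_repeats`` stochastic repeats)."""
    cfg = config.nfkb
    t = nfkb_topology(True)
    rows = []
    for point, inv_K in enumerate(cfg.inv_K_CA_values):
        p = nfkb_parameters(inv_K)
        traj = simulate_deterministic(t, p)
        feats = detect_oscillation(traj)
        if not feats.oscillatory:
            log.warning("sweep point 1/K_CA=%g lost oscillation; flagged", inv_K)
            rows.append({"inv_K_CA": inv_K, "oscillatory": False})
            continue
        x0 = state_at_b_peak(traj)
        row = {
            "inv_K_CA": inv_K,
            "oscillatory": True,
            "period_T": feats.period_T,
            "amplitude": feats.amplitude,
        }
        for mode in ("extrinsic", "intrinsic"):
            taus = np.array(
                [
                    measure_tau(
                        t, p, feats.period_T, x0, mode,
                        extrinsic_cfg=config.extrinsic,
                        intrinsic_cfg=config.intrinsic,
                        horizon_mult=cfg.horizon_mult,
                        seed=derive_seed(config.seed + cfg.seed, point, k),
                    )
                    for k in range(cfg.n_repeats)
                ]
            )
            row[f"tau_over_T_{mode}"] = float(taus.mean())
            row[f"tau_over_T_{mode}_sd"] = float(taus.std(ddof=1))
        rows.append(row)
    df = pd.DataFrame(rows)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "nfkb_sweep.csv", index=False)
    return df
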
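"""Experiment configuration, reproducible presets and the thin CLI.

A master seed deterministically derives one RNG stream per component
(network sampling, targets, trials, clamping ...), so re-running any
preset reproduces its outputs byte for byte.  Configs are plain dicts
that round-trip through JSON (TOML is accepted for reading); results are
tidy CSVs plus an HDF5 snapshot of the network.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import hippocampus as hc
from . import io as oio
from . import oscillator_net as osc
from . import tasks
from .params import GRID_MS, MAIN_SRNN, ConfigurationError
from .tasks import ExperimentProtocol

__all__ = [
    "ExperimentConfig", "derive_seed", "run_experiment", "make_fixtures",
    "main",
]

log = logging.getLogger("oscmux")

PROTOCOLS = ("train", "clamp", "multitask", "capacity", "rescale",
             "hippocampus", "screen-oscillators", "simulate", "speech")

_SCHEMA = {
    "protocol": str, "seed": int, "out_dir": str,
}


def derive_seed(master: int, name: str) -> int:
    """Stable per-component seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(name.encode())) % (2 ** 31)


@dataclass
class ExperimentConfig:
    """A named protocol plus its knobs; round-trips through JSON."""

    protocol: str
    seed: int = 0
    out_dir: str = "results"
    size: Optional[int] = None
    freqs: Optional[Sequence[float]] = None
    n_inp: int = 2
    f_range: Sequence[float] = (4.0, 5.0)
    amplitude: float = 30.0
    n_epochs: int = 10
    trial_duration: float = 1000.0
    target_cutoff: float = 6.0
    noise_sigma: float = 0.0
    fractions: Sequence[float] = (0.0, 0.05, 0.1, 0.2, 0.4)
    factors: Sequence[float] = (0.75, 1.0, 1.5, 2.0, 3.0)
    durations: Sequence[float] = (1000.0, 3000.0, 7000.0)
    cutoffs: Sequence[float] = (6.0, 30.0)
    tau_in_means: Sequence[float] = (70.0, 100.0, 130.0)
    replay_factor: float = 0.15
    reverse: bool = False
    wav: Optional[str] = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(
                f"unknown protocol {self.protocol!r}; "
                f"expected one of {PROTOCOLS}"
            )

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        p = Path(path)
        if p.suffix == ".toml":
            import tomllib

            data = tomllib.loads(p.read_text())
        else:
            data = json.loads(p.read_text())
        known = {f for f in cls.__dataclass_fields__}
        bad = [k for k in data if k not in known]
        if bad:
            raise ConfigurationError(
                f"unknown config key(s): {', '.join(sorted(bad))}"
            )
        if "protocol" not in data:
            raise ConfigurationError("config missing required key 'protocol'")
        return cls(**data)

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=2, sort_keys=True)


def make_fixtures(scale: str = "tiny") -> dict:
    """Stock configurations: tiny (unit tests), small (reduced-scale
    experiments), paper (stock-table defaults)."""
    if scale == "tiny":
        return dict(size=100, n_epochs=3, trial_duration=500.0,
                    osc_size=100, n_place=4, lap_duration=1000.0)
    if scale == "small":
        return dict(size=500, n_epochs=10, trial_duration=1000.0,
                    osc_size=250, n_place=10, lap_duration=5000.0)
    if scale == "paper":
        return dict(size=MAIN_SRNN.N, n_epochs=10, trial_duration=1000.0,
                    osc_size=500, n_place=10, lap_duration=5000.0)
    raise ConfigurationError(f"unknown fixture scale {scale!r}")


def _build_system(cfg: ExperimentConfig, master: int) -> tasks.DrivenNetwork:
    return tasks.build_driven_network(
        size=cfg.size, freqs=cfg.freqs, n_inp=cfg.n_inp,
        f_range=tuple(cfg.f_range), A=cfg.amplitude,
        seed=derive_seed(master, "network"),
    )


def _protocol(cfg: ExperimentConfig, master: int) -> ExperimentProtocol:
    return ExperimentProtocol(
        n_epochs=cfg.n_epochs, trial_duration=cfg.trial_duration,
        seed=derive_seed(master, "trials"), noise_sigma=cfg.noise_sigma,
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a named protocol; write CSV summaries and a snapshot."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed
    log.info("oscmux protocol=%s seed=%d", config.protocol, master)
    (out / "config.json").write_text(config.to_json())
    results: dict = {}

    if config.protocol in ("train", "clamp", "rescale", "simulate"):
        system = _build_system(config, master)
        if config.protocol == "simulate":
            state = system.fresh_state(derive_seed(master, "init"))
            spikes, traces = system.simulate_trial(
                state, config.trial_duration)
            spikes.to_csv(out / "spikes.csv")
            oio.save_snapshot(out / "snapshot.h5", system.population,
                              system.network.W, system.bank,
                              system.projection)
            results["spikes"] = spikes
            return results
        target = tasks.make_filtered_noise_target(
            config.trial_duration, cutoff=config.target_cutoff,
            seed=derive_seed(master, "target"))
        res = tasks.train_network(system, target, _protocol(config, master))
        res.history.to_csv(out / "history.csv", index=False)
        oio.save_snapshot(out / "snapshot.h5", system.population,
                          system.network.W, system.bank, system.projection,
                          W_out=res.rls.W_out, seeds={"master": master})
        results["train"] = res
        if config.protocol == "clamp":
            curve = tasks.clamping_curve(
                res, config.fractions, seed=derive_seed(master, "clamp"))
            curve.to_csv(out / "clamping.csv", index=False)
            results["clamping"] = curve
        elif config.protocol == "rescale":
            resc = tasks.rescaling_experiment(
                res, config.factors, noise_sigmas=(config.noise_sigma,),
                seed=derive_seed(master, "rescale"))
            resc.to_frame().to_csv(out / "rescaling.csv", index=False)
            results["rescaling"] = resc

    elif config.protocol == "multitask":
        system = _build_system(config, master)
        rng = np.random.default_rng(derive_seed(master, "phases"))
        configs = [rng.uniform(-np.pi, np.pi, system.bank.n_inp)
                   for _ in range(2)]
        targets = [
            tasks.make_shape_target("circle", config.trial_duration),
            tasks.make_shape_target("star", config.trial_duration),
        ]
        mt = tasks.multitask_train(system, configs, targets,
                                   _protocol(config, master))
        import pandas as pd

        pd.DataFrame({"task": ["circle", "star"],
                      "test_r": mt["test_r"],
                      "unseen_r": mt["unseen_r"]}).to_csv(
            out / "multitask.csv", index=False)
        results["multitask"] = mt

    elif config.protocol == "capacity":
        grid = tasks.capacity_map(config.durations, config.cutoffs,
                                  _protocol(config, master),
                                  size=config.size)
        grid.to_csv(out / "capacity.csv", index=False)
        results["capacity"] = grid

    elif config.protocol == "screen-oscillators":
        import pandas as pd

        rows = []
        for i, tau in enumerate(config.tau_in_means):
            o = osc.build_oscillator(
                tau_in_mean=tau, size=config.size,
                seed=derive_seed(master, f"osc{i}"))
            rep = osc.stability_screen(o, duration=config.trial_duration)
            _, tr = osc.simulate_oscillator(
                o, o.cue.t_end_ex, seed=derive_seed(master, f"osc-run{i}"))
            i0 = int(o.cue.t_end_in / 0.05)  # post-transient cued window
            f = osc.measure_frequency(tr["rate"][i0:], 0.05, f_min=2.0,
                                      f_max=100.0)
            rows.append({"tau_in": tau, "stable": rep.stable,
                         "mean_correlation": rep.mean_correlation,
                         "frequency_hz": f})
        df = pd.DataFrame(rows)
        df.to_csv(out / "oscillators.csv", index=False)
        results["screen"] = df

    elif config.protocol == "hippocampus":
        hcfg = hc.HippocampalConfig(
            size=config.size or hc.HippocampalConfig.size)
        model = hc.build_hippocampal_model(
            hcfg, seed=derive_seed(master, "hippocampus"))
        M, spikes, traces = hc.training_lap(
            model, seed=derive_seed(master, "lap"))
        recall = hc.test_recall(model, M,
                                seed=derive_seed(master, "recall"))
        rep = hc.replay(model, M, factor=config.replay_factor,
                        reverse=config.reverse,
                        seed=derive_seed(master, "replay"))
        spikes.to_csv(out / "training_spikes.csv")
        recall["spikes"].to_csv(out / "recall_spikes.csv")
        import pandas as pd

        pd.DataFrame({
            "cell": model.place_cells,
            "onset_ms": hcfg.onsets(),
            "recall_peak_ms": recall["peak_times"],
            "replay_peak_ms": rep["peak_times"],
        }).to_csv(out / "place_cells.csv", index=False)
        results.update(model=model, M=M, recall=recall, replay=rep)

    elif config.protocol == "speech":
        from . import audio

        if config.wav:
            wave, sr = audio.read_wav(config.wav)
        else:
            wave, sr = audio.synth_word(seed=derive_seed(master, "word"))
        system = _build_system(config, master)
        sp = audio.speech_experiment(system, wave, sr, config.factors,
                                     _protocol(config, master))
        import pandas as pd

        pd.DataFrame({"factor": sp["factors"],
                      "mean_channel_r": sp["mean_r_by_factor"]}).to_csv(
            out / "speech.csv", index=False)
        results["speech"] = sp

    return results


def main(argv: Optional[Sequence[str]] = None) -> int:
    parser = argparse.ArgumentParser(
        prog="oscmux",
        description="Oscillation-multiplexed spiking reservoir experiments",
    )
    parser.add_argument("protocol", choices=PROTOCOLS)
    parser.add_argument("--config", type=str, default=None,
                        help="JSON/TOML config file")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=str, default="results")
    parser.add_argument("--size", type=int, default=None)
    parser.add_argument("--factor", type=float, default=0.15,
                        help="replay compression factor (hippocampus)")
    parser.add_argument("--reverse", action="store_true",
                        help="reverse the compressed replay input")
    parser.add_argument("--wav", type=str, default=None,
                        help="mono WAV file for the speech task")
    parser.add_argument("--factors", type=str, default=None,
                        help="comma-separated rescaling factors")
    args = parser.parse_args(argv)

    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    if args.config:
        cfg = ExperimentConfig.from_file(args.config)
        cfg.protocol = args.protocol
    else:
        cfg = ExperimentConfig(protocol=args.protocol)
    cfg.seed = args.seed
    cfg.out_dir = args.out
    if args.size is not None:
        cfg.size = args.size
    cfg.replay_factor = args.factor
    cfg.reverse = args.reverse
    if args.wav:
        cfg.wav = args.wav
    if args.factors:
        cfg.factors = tuple(float(x) for x in args.factors.split(","))
    try:
        run_experiment(cfg)
    except ConfigurationError as exc:
        log.error("%s", exc)
        return 2
    return 0


if __name__ == "__main__":
    sys.exit(main())
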
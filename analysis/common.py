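"""Shared argument parsing for the numbered analysis drivers."""

import argparse

from lptcnet.experiments import ExperimentConfig


def make_config(experiment: str, description: str,
                default_trials: int) -> ExperimentConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--trials", type=int, default=default_trials)
    parser.add_argument("--duration", type=float, default=24000.0,
                        help="trial length in ms")
    parser.add_argument("--out", default="results",
                        help="output directory for CSV tables and the "
                             "JSON summary")
    parser.add_argument("--fast", action="store_true",
                        help="8 s trials (wider statistical tolerances)")
    args = parser.parse_args()
    return ExperimentConfig(experiment, n_trials=args.trials,
                            duration=args.duration, seed=args.seed,
                            out_dir=args.out, fast=args.fast)
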
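#!/usr/bin/env python
"""Generate the two synthetic study cores.

Builds the remote-highland and peri-urban preset cores (with measurement
noise) plus a noise-free copy of each, and writes the core tables and
ground-truth tables under results/cores/.
"""

from pathlib import Path

from sedflux.synthetic import build_synthetic_core, preset

SEED = 20140701
OUT = Path(__file__).resolve().parents[1] / "results" / "cores"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("remote-highland", "peri-urban"):
        for variant, scenario in (
            ("", preset(name)),
            ("_noisefree", preset(name).noise_free()),
        ):
            profile, truth = build_synthetic_core(scenario, SEED)
            core = OUT / f"{name}{variant}_core.csv"
            profile.data.to_csv(core, index=False)
            truth.export(OUT / f"{name}{variant}_truth.csv")
            print(
                f"{name}{variant}: {profile.n_layers} layers, "
                f"elements {', '.join(profile.elements)} -> {core.name}"
            )


if __name__ == "__main__":
    main()
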
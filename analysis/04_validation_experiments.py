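#!/usr/bin/env python
"""Validation experiments: planted-structure recovery and null calibration.

Recovery: groups with genuinely different planted small-world networks
(rewire 0.05 vs 0.5) — does the estimated cosine+TMFG network reproduce the
planted metric orderings?  Calibration: identical planted networks for both
groups — are the bootstrap t statistics free of systematic direction?

A headline finding of these experiments is NEGATIVE for one metric: the
TMFG backbone's average local clustering does not track latent small-world
rewiring (the ordering inverts), while the ASPL and Q orderings are
recovered reliably.  See docs/methods.md for the analysis.
"""

from pathlib import Path

from fluencynet.experiments import calibration_experiment, recovery_experiment

OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rec = recovery_experiment(n_replications=20, seed=1)
    rec.to_csv(OUT / "recovery.csv", index=False)
    print("planted-structure recovery over 20 replications "
          "(high group = rewire 0.05, low = 0.5):")
    for m in ("cc", "aspl", "q"):
        n_ok = int(rec[f"correct_order_{m}"].sum())
        print(f"  {m:5s}: planted ordering recovered in {n_ok}/20")
    print("  (cc inversion is systematic; the TMFG filter's clustering "
          "does not follow latent rewiring)")

    cal = calibration_experiment(n_replications=20, seed=1)
    cal.to_csv(OUT / "calibration.csv", index=False)
    share_pos = float((cal["t"] > 0).mean())
    print(f"\nnull calibration over 20 replications: mean t = "
          f"{cal['t'].mean():+.3f}, {share_pos:.0%} positive signs")


if __name__ == "__main__":
    main()
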
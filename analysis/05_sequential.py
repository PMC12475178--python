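#!/usr/bin/env python
"""Forward/reverse cumulative-bias analysis with permutation bands.

For each adaptor-relative standard orientation, accumulates +-1-coded
responses forward from trial 1 and in reverse from trial 300, builds the
1000-permutation direction-randomised null band, and flags trials where the
mean accumulation escapes the 95% band (a start-vs-end bias difference).
Also writes the absolute-standard folding (+-S strata combined).
"""

from pathlib import Path

from tiltfilm.io import read_trials
from tiltfilm.sequential import (fold_absolute_standard, result_table,
                                 sequential_analysis)

ROOT = Path(__file__).resolve().parents[1] / "results"
N_PERM = 1000
SEED = 3


def main() -> None:
    completed = read_trials(ROOT / "responses" / "responses.csv")
    out = ROOT / "sequential"
    out.mkdir(parents=True, exist_ok=True)

    results = sequential_analysis(completed, n_perm=N_PERM, seed=SEED)
    for rel, res in sorted(results.items()):
        result_table(res).to_csv(out / f"rel_standard_{rel:+.1f}.csv",
                                 index=False)
        print(f"relative standard {rel:+5.1f} deg: "
              f"{int(res.flags.sum()):3d}/{res.n_trials} trials outside the "
              f"95% band")

    for mag in (22.5, 67.5):
        folded = fold_absolute_standard(results[mag], results[-mag])
        result_table(folded).to_csv(
            out / f"abs_standard_{mag:.1f}.csv", index=False)
        print(f"absolute standard {mag:5.1f} deg (folded): "
              f"{int(folded.flags.sum()):3d}/{folded.n_trials} outside")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(4, 1, figsize=(7, 10), sharex=True)
        for ax, (rel, res) in zip(axes, sorted(results.items())):
            t = range(1, res.n_trials + 1)
            ax.plot(t, res.forward, color="#d46", label="forward")
            ax.plot(t, res.reverse, color="#3a6", label="reverse")
            ax.plot(t, res.ci_lo, "k", lw=0.8)
            ax.plot(t, res.ci_hi, "k", lw=0.8)
            flag_idx = [i + 1 for i, f in enumerate(res.flags) if f]
            ax.plot(flag_idx, [ax.get_ylim()[1] * 0.9] * len(flag_idx), "k*",
                    ms=4)
            ax.set_ylabel(f"bias ({rel:+.1f}°)")
        axes[0].legend(loc="upper right")
        axes[-1].set_xlabel("trial")
        fig.tight_layout()
        fig.savefig(out / "accumulation.png", dpi=120)
        print(f"figure -> {out / 'accumulation.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
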
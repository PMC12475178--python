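#!/usr/bin/env python
"""Build the full counterbalanced cohort schedule at study scale.

24 participants, three sessions each (practice + 600 baseline trials, then
two adaptation sessions of 120 clip-blocks x 5 trials).  Writes the
schedule CSV and prints the design arithmetic it reproduces.
"""

from pathlib import Path

from tiltfilm.design import DesignSpec, build_cohort_schedule
from tiltfilm.io import write_trials

OUT = Path(__file__).resolve().parents[1] / "results" / "design"
N_PARTICIPANTS = 24
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = DesignSpec()
    pids = [f"p{i:02d}" for i in range(1, N_PARTICIPANTS + 1)]
    schedule = build_cohort_schedule(spec, pids, SEED)
    write_trials(schedule, OUT / "schedule.csv")

    main_trials = schedule.loc[schedule["phase"] == "main"]
    adapt = main_trials.loc[main_trials["session"] != "baseline"]
    print(f"participants:                {N_PARTICIPANTS}")
    print(f"total scheduled trials:      {len(schedule)}")
    print(f"experimental trials/session: "
          f"{len(main_trials) // (3 * N_PARTICIPANTS)}")
    print(f"trials per standard/session: "
          f"{adapt.groupby(['participant', 'session', 'standard_deg']).size().iloc[0]}")
    print(f"blocks of five per session:  "
          f"{adapt.groupby(['participant', 'session'])['block'].nunique().iloc[0]}")
    print(f"film clips per session:      {spec.clips_per_session} "
          f"({spec.viewing_minutes_per_session:.2f} min viewing)")
    print(f"schedule -> {OUT / 'schedule.csv'}")


if __name__ == "__main__":
    main()
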
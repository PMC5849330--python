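"""Regenerate the packaged dive-cycle fixture and report its accounting.

Writes the deterministic fixture to the package data directory (the copy
shipped with the library) and a working copy under results/.
"""

from pathlib import Path

from franciscana_availability import filter_cycles, summarize, write_cycles_csv
from franciscana_availability.fixture import build_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sessions = build_fixture()
    pkg_csv = ROOT / "src" / "franciscana_availability" / "data" / "fixture_cycles.csv"
    pkg_csv.parent.mkdir(parents=True, exist_ok=True)
    write_cycles_csv(sessions, pkg_csv)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_cycles_csv(sessions, out / "fixture_cycles.csv")

    kept, report = filter_cycles(sessions)
    s = summarize(kept)
    print(f"fixture: {report.n_cycles_in} cycles / {report.n_groups_in} groups")
    print(
        f"after filtering ({report.n_reaction_removed} reaction, "
        f"{report.n_confidence_removed} low-confidence): "
        f"{report.n_cycles_out} cycles / {report.n_groups_out} groups "
        f"({s.mean_cycles_per_group:.2f} cycles/group)"
    )
    print(
        f"pooled means: E(s) = {s.mean_surface_s:.2f} s (SD {s.sd_surface_s:.2f}), "
        f"E(d) = {s.mean_dive_s:.2f} s (SD {s.sd_dive_s:.2f})"
    )
    print(f"mean proportion at surface: {s.mean_proportion:.2f}")


if __name__ == "__main__":
    main()
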
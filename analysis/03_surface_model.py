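"""Mixed-model selection on the fixture's log proportion-at-surface.

Checks whether the AR-1 residual structure is supported, fits all 32
predictor subsets, and writes the AIC ranking and the model-averaged
coefficients with relative importance.
"""

from pathlib import Path

from franciscana_availability import (
    fit_all_subsets,
    filter_cycles,
    make_fixture,
    prepare_response,
    select_autocorrelation,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    kept, _ = filter_cycles(make_fixture())
    table = prepare_response(kept)

    ac = select_autocorrelation(table)
    pref = "with" if ac.prefers_ar1 else "without"
    print(
        f"global model AIC: {ac.aic_with_ar1:.2f} with AR-1 vs "
        f"{ac.aic_without:.2f} without (prefers {pref}, phi = {ac.phi:.2f})"
    )

    summary = fit_all_subsets(table)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    mt = summary.model_table()
    ct = summary.coefficient_table()
    mt.to_csv(out / "model_selection.csv", index=False)
    ct.to_csv(out / "model_averaged_coefficients.csv", index=False)

    print("\ntop models (delta AIC <= 2):")
    print(mt[mt.delta_aic <= 2].round(3).to_string(index=False))
    print("\nmodel-averaged coefficients:")
    print(ct.round(4).to_string(index=False))
    best = summary.best
    print(
        f"\nbest model: {best.model.label} "
        f"(AIC {best.aic:.2f}, phi {best.phi[0]:.2f})"
    )


if __name__ == "__main__":
    main()
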
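"""Stimulation scenarios: oxidative vs glycolytic phenotypes.

Runs the stimulation library on the calibrated reference cell and reports
basal and stimulated steady-state fluxes with percent changes:

* the oxidative cell (net lactate importer, r = 0.75 at rest) responds to a
  combined transport + extracellular-lactate + oxidative-capacity
  stimulation with ~+47% oxidative flux and ~+45% lactate uptake;
* cutting PDH capacity to 0.3x and NADH-shuttle capacity to 0.2x converts
  the same cell into a net lactate exporter (glycolytic phenotype) whose
  stimulation yields a modest oxidative response (~+11%) but a prominent
  surge in lactate release (~+91%);
* the in-vivo-calibrated cell (r = 2.2, L_e = 1.1 mM) reaches ~+86%
  oxidative flux under the combined stimulation.
"""

from pathlib import Path

import pandas as pd

from lacflux.config import oxidative_reference
from lacflux.scenarios import builtin_scenarios, run_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"

SCENARIOS = [
    "fig2A_ctrl", "fig2A_mct", "fig2A_le", "fig2A_combined",
    "fig2B_ctrl", "fig2B_mct", "fig2B_le", "fig2B_combined",
    "fig4A_invivo", "fig4A_invitro", "fig4A_invitro_high_le",
    "fig4A_invitro_low_glyco",
    "fig4B_ctrl", "fig4B_mct", "fig4B_le", "fig4B_combined",
    "figS2_mct", "figS2_le", "figS2_combined", "figS2_combined_glyco",
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = oxidative_reference()
    lib = builtin_scenarios()
    rows = []
    for name in SCENARIOS:
        res = run_scenario(cfg.parameters, cfg.environment, cfg.options,
                           lib[name])
        rows.append({
            "scenario": name,
            "basal_J_MCT": res.basal.fluxes.J_MCT,
            "basal_J_PDH": res.basal.fluxes.J_PDH,
            "basal_r": res.basal.r,
            "stim_J_MCT": res.stimulated.fluxes.J_MCT,
            "stim_J_PDH": res.stimulated.fluxes.J_PDH,
            "stim_r": res.stimulated.r,
            "pct_J_MCT": round(res.pct_change["J_MCT"]),
            "pct_J_glyco": round(res.pct_change["J_glyco"]),
            "pct_J_PDH": round(res.pct_change["J_PDH"]),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "scenario_responses.csv", index=False)
    print(table[["scenario", "basal_r", "pct_J_MCT", "pct_J_glyco",
                 "pct_J_PDH"]].to_string(index=False))
    print(f"\nwrote {RESULTS / 'scenario_responses.csv'}")


if __name__ == "__main__":
    main()
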
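"""Multiple imputation of a heavily left-censored water panel.

Builds a complete two-substance panel with known values (correlation 0.9 on
the log scale), censors it artificially at DL thresholds of 3 and 5 ug/L
(~82% / ~88% censored), and compares bootstrap-EM multiple imputation with
the naive DL/2 and DL/sqrt(2) substitutions by their error on the censored
cells.
"""

from geoexpose.censoring import bias_simulation
from geoexpose.scenario import simulate_water_panel, validation_panel_config

cfg = validation_panel_config(seed=1)
panel, _, _ = simulate_water_panel(cfg)
print(f"panel: {len(panel)} records, {panel['substance'].nunique()} substances")

table = bias_simulation(panel, thresholds=[3.0, 5.0], target_substance="S0",
                        m=8, seed=2)
print(table.round(3).to_string(index=False))
print(
    "\nAME/RMSE are the mean absolute and root-mean-square differences\n"
    "between each method's completed values and the known truth on the\n"
    "censored cells only. Imputation exploits the correlated second\n"
    "substance and should show by far the smallest bias at both censoring\n"
    "levels, the ordering that motivates using it over constant substitution."
)
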
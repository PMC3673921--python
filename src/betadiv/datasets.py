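"""Built-in worked-example datasets.

The single dataset here is the published estuarine/catchment characteristics
table for the nine North Island (New Zealand) estuaries the analysis was
designed around: morphology (areas, shore length, shore complexity SC,
closure index CI), hydrodynamics (river inflow ratio, discharge, rainfall,
runoff, tide range, % intertidal) and catchment land use (% natural,
pastoral, urban, exotic cover).  It drives the ordination and collinearity
worked examples and makes them runnable offline.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["estuary_catchment_table", "COLLINEAR_EXCLUSIONS"]

_TABLE_CSV = """\
estuary,estuary_area_km2,catchment_area_km2,shore_length_km,shore_complexity,closure_index,river_inflow,river_discharge_cumecs,rainfall_mm_yr,runoff_mm_km2,tide_range_m,intertidal_pct,natural_pct,pastoral_pct,urban_pct,exotic_pct
Mangemangeroa,0.6,10.0,7.4,0.34,0.09,0.02,0.4,1208,300,2.4,86.9,26.6,69.9,3.4,0.09
Okura,1.4,27.4,12.7,0.31,0.04,0.06,1.2,1401,457,2.2,79.3,40.7,36.9,0.6,21.8
Parekura,3.6,23.2,14.4,0.45,0.05,0,1.2,1598,664,1.6,36.9,77.3,17.1,0,5.6
Puhoi,1.7,43.0,18.7,0.25,0,0.03,2.2,1600,764,2.1,70.6,32.8,55.5,0,11.4
Tamaki,16.9,108.8,94.6,0.15,0.02,0.004,4.1,1208,250,2.4,40.0,1.96,24.7,73.1,0.2
Waitemata,78.8,427.3,260.1,0.12,0.01,0.003,19.7,1468,430,2.3,36.2,18.6,34.5,42.6,4.2
Waiwera,1.0,37.9,11.7,0.3,0.001,0.04,1.9,1577,643,2.1,64.5,47.1,52.3,0.4,0.3
Whananaki,2.1,53.9,16.8,0.3,0.01,0.04,2.9,1731,778,1.6,75.3,65.1,34.5,0,0.2
Whangateau,7.5,42.4,31.9,0.3,0.01,0.01,2.1,1596,553,1.9,85.4,19.6,75.6,0.9,3.6
"""

#: Estuary-scale variables dropped before ordination/regression in the
#: original analysis after the Spearman collinearity screen flagged them
#: (each is rank-correlated > 0.8 with retained variables such as estuary
#: area).  The screen reports flagged pairs; which member of a redundant
#: cluster to keep is an expert choice, recorded here as data.
COLLINEAR_EXCLUSIONS = (
    "shore_length_km",
    "catchment_area_km2",
    "river_discharge_cumecs",
)


def estuary_catchment_table() -> pd.DataFrame:
    """The 9-estuary x 15-variable characteristics table (index: estuary)."""
    return pd.read_csv(io.StringIO(_TABLE_CSV), index_col="estuary")
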
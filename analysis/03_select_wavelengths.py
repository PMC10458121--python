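"""Screen feature wavelengths with CARS, SPA, BOSS and IVSO.

The four selectors run on the winner-preprocessed soybean set (every 10th
wavelength enters the search). The summary table reports how many
wavelengths each method keeps, the percent of the full spectrum that
represents, and how the picks distribute over the UV/Vis/NIR bands —
CARS/BOSS/IVSO concentrate near the informative Vis bands while SPA's
collinearity-driven chain scatters.
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from study_config import SEED, STUDY  # noqa: E402

from adulterspec.feature_selection import selection_summary
from adulterspec.pipeline import compare_preprocessing, run_selector
from adulterspec.pipeline import _winning_spec  # stage reuse
from adulterspec.preprocessing import preprocess
from adulterspec.spectra_core import WavelengthGrid, default_grid
from adulterspec.synthetic_data import MixDesign, generate_full_study

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    grid = default_grid(STUDY.n_grid_points)
    ds = generate_full_study(MixDesign(seed=SEED), grid)["soybean"]
    win = _winning_spec(compare_preprocessing(ds, seed=SEED))
    print(f"preprocessing: {win.label}")

    thin = np.arange(0, len(grid), STUDY.wavelength_step)
    thin_grid = WavelengthGrid(grid.values[thin])
    X = preprocess(ds, win).X[:, thin]

    results = [run_selector(m, X, ds.y, STUDY, SEED)
               for m in ("cars", "spa", "boss", "ivso")]
    table = selection_summary(results, thin_grid)
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "03_selection_summary.csv", index=False)
    for res in results:
        with open(ROOT / "results" / f"03_selection_{res.method}.json", "w",
                  encoding="utf-8") as fh:
            json.dump(res.to_dict(thin_grid), fh, indent=2)
            fh.write("\n")

    print(table.to_string(index=False))
    best = table.loc[table["best_rmsecv"].idxmin(), "method"]
    print(f"\nlowest selection RMSECV: {best}")


if __name__ == "__main__":
    main()
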
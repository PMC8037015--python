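#!/usr/bin/env python
"""Rerun the compound-specific derivation on the published Zenodo dataset.

This script is OPTIONAL and requires data that is not shipped with the
package.  Download the deposited dataset

    Baderna, D., & Benfenati, E. (2021). Curated Envirotox database and
    compound specific Human-Biota TTC from the LIFE+ Vermeer project
    (Version 1.0) [Data set]. Zenodo. https://doi.org/10.5281/zenodo.4643745

and export two CSV files in the package's input schemas:

    pnec_table.csv    chemical_id, verhaar_class, pnec, unit
    hazard_table.csv  chemical_id, noael, adi, tdi, rfd, bmd,
                      slope_factor, cancer_dw_conc, cancer_dw_unit
                      (dose columns in mg/kg bw/day; blanks = absent)

Then run:

    python scripts/rerun_zenodo.py pnec_table.csv hazard_table.csv out.csv

which applies the compound-specific pipeline (cancer route when a slope
factor or risk-level concentration is present, NOAEL/100 otherwise, the
minimum rule against the PNEC) and prints summary statistics comparable to
the published ones: the threshold range, the non-carcinogen count, and the
fraction of carcinogens limited by the human branch.
"""

from __future__ import annotations

import csv
import sys
from pathlib import Path

from hbttc.combine import compound_hbttc
from hbttc.core import ExposureDefaults, HazardProfile
from hbttc.io import read_hazard_table, read_pnec_table


def main(pnec_path: str, hazard_path: str, out_path: str) -> None:
    pnecs, perr = read_pnec_table(pnec_path)
    hazards, herr = read_hazard_table(hazard_path)
    for err in perr + herr:
        print(f"warning: line {err.line}: {err.message}", file=sys.stderr)

    defaults = ExposureDefaults()
    pnec_by_id = {cid: conc for cid, _, conc in pnecs}
    results = []
    carcinogens = []
    from hbttc.human_qs import compound_qs

    for row in hazards:
        cid = row.pop("chemical_id")
        if cid not in pnec_by_id:
            continue
        profile = HazardProfile(**row)
        qs = compound_qs(profile, defaults)
        combined = compound_hbttc(pnec_by_id[cid], qs, cid)
        results.append(combined)
        if profile.is_carcinogen:
            carcinogens.append(combined)

    with Path(out_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chemical_id", "hbttc_mg_per_l", "limiting_branch"])
        for r in results:
            writer.writerow([r.chemical_id, repr(r.value.mg_per_l), r.limiting_branch])

    values = sorted(r.value.mg_per_l for r in results)
    n_carc = len(carcinogens)
    n_human_limited = sum(1 for r in carcinogens if r.limiting_branch == "human")
    print(f"compounds: {len(results)}")
    print(f"range: {values[0]:.3e} - {values[-1]:.3e} mg/L")
    print(f"non-carcinogens: {len(results) - n_carc}")
    print(f"carcinogens human-limited: {n_human_limited}/{n_carc}")


if __name__ == "__main__":
    if len(sys.argv) != 4:
        print(__doc__, file=sys.stderr)
        sys.exit(2)
    main(*sys.argv[1:])
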
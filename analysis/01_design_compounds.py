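"""Enumerate the amide coupling products of the G1-PABA scaffold and profile
them: elemental formula, exact mass, ESI adduct masses and drug-likeness
properties.  Writes results/compound_design.csv."""

from pathlib import Path

import pandas as pd

from dualvs.chem import (
    adduct_mass,
    compute_properties,
    enumerate_amide_products,
    monoisotopic_mass,
)
from dualvs.reference import g1_paba, sulfonamide_nucleophiles
from dualvs.scoring import lipinski_points

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    products = enumerate_amide_products(g1_paba(), sulfonamide_nucleophiles())
    rows = []
    for product in products:
        formula = product.formula()
        props = compute_properties(product)
        rows.append(
            {
                "product": product.id,
                "formula": formula.hill(),
                "monoisotopic_mass": round(monoisotopic_mass(formula), 4),
                "m_plus_h": round(adduct_mass(formula, "[M+H]+"), 4),
                "mw": round(props.molecular_weight, 2),
                "logp": round(props.log_p, 2),
                "hbd": props.hbd,
                "hba": props.hba,
                "tpsa": round(props.tpsa, 2),
                "lipinski_points": lipinski_points(props),
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "compound_design.csv", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
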
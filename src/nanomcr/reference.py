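"""Small built-in reference panel for comparative profiling.

Comparative analyses (shape triangles, KS distribution tests, similarity
matrices) need a reference compound set alongside the enumerated library.
Full reference collections (e.g. all FDA-approved drugs) are supplied by
the user; this module only ships a small demonstration panel of well-known
approved-drug structures so examples and tests run self-contained.
"""

DEMO_REFERENCE_DRUGS: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "caffeine": "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "metoprolol": "COCCc1ccc(OCC(O)CNC(C)C)cc1",
    "lidocaine": "CCN(CC)CC(=O)Nc1c(C)cccc1C",
    "procaine": "CCN(CC)CCOC(=O)c1ccc(N)cc1",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "diazepam": "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",
    "haloperidol": "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",
    "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "sertraline": "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",
    "imipramine": "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "amitriptyline": "CN(C)CCC=C1c2ccccc2CCc2ccccc21",
    "carbamazepine": "NC(=O)N1c2ccccc2C=Cc2ccccc21",
    "phenytoin": "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",
    "ketamine": "CNC1(c2ccccc2Cl)CCCCC1=O",
    "morphine": "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",
    "codeine": "COc1ccc2CC3C4C=CC(O)C5Oc1c2C45CCN3C",
    "tramadol": "CN(C)CC1CCCCC1(O)c1cccc(OC)c1",
    "fentanyl": "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "metformin": "CN(C)C(=N)NC(=N)N",
    "glibenclamide": "COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1",
    "atorvastatin": "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O",
    "simvastatin": "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21",
    "amoxicillin": "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O",
    "ciprofloxacin": "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
    "trimethoprim": "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",
    "sulfamethoxazole": "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
    "fluconazole": "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1Cl",
    "omeprazole": "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1",
    "ranitidine": "CNC(=CN(=O)=O)NCCSCc1ccc(CN(C)C)o1",
    "loratadine": "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1",
    "cetirizine": "OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1",
    "diphenhydramine": "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "salbutamol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "theophylline": "Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "prednisone": "CC12CC(=O)C3C(CCC4=CC(=O)C=CC43C)C1CCC2(O)C(=O)CO",
    "dexamethasone": "CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO",
    "tamoxifen": "CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "methotrexate": "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1",
    "praziquantel": "O=C1CN2CCc3ccccc3C2CN1C(=O)C1CCCCC1",
    "doxapram": "CCN1CC(CCN2CCOCC2)C(c2ccccc2)(c2ccccc2)C1=O",
    "levodopa": "NC(Cc1ccc(O)c(O)c1)C(=O)O",
    "gabapentin": "NCC1(CC(=O)O)CCCCC1",
}


def reference_smiles() -> list[str]:
    return list(DEMO_REFERENCE_DRUGS.values())
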
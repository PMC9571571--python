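"""Physicochemical filtering of candidate compounds (rule-of-five stage).

Descriptors are computed from SMILES with RDKit on the largest connected
fragment (salt/solvate fragments are dropped; e.g. ammonium counter-ions on
glycyrrhizin). Lipinski's rule of five is applied in its classic form:

* molecular weight <= 500 Da,
* logP <= 5 (Crippen estimate; note that logP is engine-dependent),
* H-bond donors (OH + NH hydrogens) <= 5,
* H-bond acceptors (N + O atom count) <= 10,

each exceeded threshold counting as one violation. TPSA follows the Ertl
fragment scheme including the S/P contributions, after re-perceiving
aromaticity with the MDL model — the combination that matches the values
printed by the common web calculators (a lactone oxygen counts as an ether,
a sulfone sulfur contributes its polar term).

Blood-brain-barrier (BBB+/BBB-) and pathogenicity flags come from external
predictors and are consumed as annotations, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors, rdmolops

from .errors import ChemParseError, InputError, ParseError

RDLogger.DisableLog("rdApp.*")

LIPINSKI_MW = 500.0
LIPINSKI_LOGP = 5.0
LIPINSKI_HBD = 5
LIPINSKI_HBA = 10


@dataclass
class CompoundRecord:
    name: str
    smiles: str
    annotations: dict = field(default_factory=dict)


@dataclass
class DescriptorSet:
    mol_weight: float  # Da, average atomic masses
    logp: float  # Crippen octanol-water partition estimate
    tpsa: float  # A^2, Ertl topological polar surface area (with S/P terms)
    hbd: int  # Lipinski donors: OH + NH hydrogens
    hba: int  # Lipinski acceptors: N + O atoms
    violations: int = 0

    def __post_init__(self):
        if self.violations == 0:
            self.violations = count_violations(self)


@dataclass
class FilterCriteria:
    max_violations: int = 4
    require_bbb_positive: bool = False
    exclude_pathogenic: bool = False

    def __post_init__(self):
        if not 0 <= self.max_violations <= 4:
            raise InputError("max_violations must lie in 0..4")


PATHOGENICITY_FLAGS = ("mutagenicity", "tumorigenicity", "irritant", "reproductive_effective")


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def largest_fragment(smiles: str) -> str:
    """Return the connected component with the most heavy atoms, as SMILES."""
    mol = _parse(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    biggest = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return Chem.MolToSmiles(biggest)


def _mdl_aromatic(mol: Chem.Mol) -> Chem.Mol:
    """Re-perceive aromaticity under the MDL model (benzenoid rings only)."""
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    rdmolops.SetAromaticity(mol, rdmolops.AromaticityModel.AROMATICITY_MDL)
    return mol


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Descriptors of the largest fragment, with the Lipinski violation count."""
    mol = _parse(largest_fragment(smiles))
    return DescriptorSet(
        mol_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        tpsa=rdMolDescriptors.CalcTPSA(_mdl_aromatic(mol), includeSandP=True),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
    )


def count_violations(d: DescriptorSet) -> int:
    """Number of exceeded rule-of-five thresholds (0..4)."""
    return int(
        (d.mol_weight > LIPINSKI_MW)
        + (d.logp > LIPINSKI_LOGP)
        + (d.hbd > LIPINSKI_HBD)
        + (d.hba > LIPINSKI_HBA)
    )


def _violations_of(record: CompoundRecord) -> int:
    if "violations" in record.annotations and record.annotations["violations"] is not None:
        return int(record.annotations["violations"])
    return compute_descriptors(record.smiles).violations


def filter_candidates(records, criteria: FilterCriteria):
    """Apply the active criteria; returns ``(kept, rejection_log)``.

    ``rejection_log`` is a list of ``(name, reason)`` pairs. The violation
    count comes from a ``violations`` annotation when present (e.g. values
    from an external property server), otherwise it is computed from the
    SMILES. BBB and pathogenicity checks require annotations; missing ones
    raise an error naming the offending compounds.
    """
    records = list(records)
    if criteria.require_bbb_positive:
        missing = [r.name for r in records if "bbb" not in r.annotations]
        if missing:
            raise InputError(f"records lacking BBB annotation: {', '.join(missing)}")
    if criteria.exclude_pathogenic:
        missing = [
            r.name
            for r in records
            if not any(f in r.annotations for f in PATHOGENICITY_FLAGS)
        ]
        if missing:
            raise InputError(
                f"records lacking pathogenicity annotations: {', '.join(missing)}"
            )
    kept, rejections = [], []
    for r in records:
        v = _violations_of(r)
        if v > criteria.max_violations:
            rejections.append((r.name, f"{v} Lipinski violations > {criteria.max_violations}"))
            continue
        if criteria.require_bbb_positive and str(r.annotations["bbb"]).strip() != "BBB+":
            rejections.append((r.name, f"not BBB+ ({r.annotations['bbb']})"))
            continue
        if criteria.exclude_pathogenic:
            flags = [
                f for f in PATHOGENICITY_FLAGS
                if str(r.annotations.get(f, "No")).strip().casefold() == "yes"
            ]
            if flags:
                rejections.append((r.name, f"pathogenicity flags: {', '.join(flags)}"))
                continue
        kept.append(r)
    return kept, rejections


# ---------------------------------------------------------------------------
# I/O

def read_compound_table(path) -> list[CompoundRecord]:
    """CSV with ``name``, ``smiles`` and optional annotation columns."""
    df = pd.read_csv(path) if _nonempty(path) else pd.DataFrame(columns=["name", "smiles"])
    cols = {c.casefold(): c for c in df.columns}
    if "smiles" not in cols or "name" not in cols:
        raise ParseError(f"{path}: requires 'name' and 'smiles' columns, got {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        ann = {
            c.casefold(): row[c]
            for c in df.columns
            if c.casefold() not in ("name", "smiles") and pd.notna(row[c])
        }
        records.append(
            CompoundRecord(name=str(row[cols["name"]]), smiles=str(row[cols["smiles"]]), annotations=ann)
        )
    return records


def _nonempty(path) -> bool:
    try:
        with open(path, encoding="utf-8") as fh:
            return bool(fh.read(1))
    except FileNotFoundError:
        raise
    return False


def write_report(records, descriptors, path) -> None:
    """Write the descriptor report CSV (one row per compound)."""
    rows = []
    for r, d in zip(records, descriptors):
        rows.append(
            {
                "name": r.name,
                "smiles": r.smiles,
                "mol_weight": round(d.mol_weight, 2),
                "logp": round(d.logp, 2),
                "tpsa": round(d.tpsa, 2),
                "hbd": d.hbd,
                "hba": d.hba,
                "violations": d.violations,
                **{k: v for k, v in r.annotations.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def case_study_compounds() -> list[CompoundRecord]:
    """The packaged Th17/depression antioxidant case-study table.

    Ten compounds with their SMILES and the externally predicted BBB,
    pathogenicity and violation annotations. The acebutolol SMILES in the
    published table is inconsistent with acebutolol itself (it encodes a
    lighter congener); the row is carried for filtering but flagged with
    ``smiles_inconsistent`` so descriptor checks can exclude it.
    """
    ref = resources.files("drugsieve") / "data" / "case_study_compounds.csv"
    with resources.as_file(ref) as p:
        return read_compound_table(p)
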
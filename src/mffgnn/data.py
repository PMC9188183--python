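"""Chemistry-aware data handling for DDI link prediction.

Parses SMILES into featurized molecular graphs (via RDKit) and into
atom-token sequences, reads/writes the drug-table and edge-list file
formats, builds transductive train/validation/test splits with matched
negative sampling, and generates synthetic interaction datasets with a
planted community structure so the full pipeline can be exercised without
external downloads.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # keep parse rejections quiet; we log our own

logger = logging.getLogger("mffgnn")

PAD_TOKEN = "<pad>"
PAD_ID = 0

# ----------------------------------------------------------------------
# featurization schema (frozen; every one-hot block sums to exactly 1)
# ----------------------------------------------------------------------

ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se"]
CHARGE_BUCKETS = [-2, -1, 0, 1, 2]  # formal charge clipped into this range
HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
MAX_DEGREE = 6

ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + len(CHARGE_BUCKETS) + 1 \
    + (len(HYBRIDIZATIONS) + 1) + (len(CHIRAL_TAGS) + 1) + (MAX_DEGREE + 1)

BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_FEATURE_DIM = len(BOND_TYPES) + 2


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    """Fixed-length atom descriptor: element, formal charge bucket,
    aromaticity, hybridization, chirality tag and heavy-atom degree."""
    sym = atom.GetSymbol()
    elem = _one_hot(ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS),
                    len(ELEMENTS) + 1)
    charge = int(np.clip(atom.GetFormalCharge(), CHARGE_BUCKETS[0], CHARGE_BUCKETS[-1]))
    chg = _one_hot(CHARGE_BUCKETS.index(charge), len(CHARGE_BUCKETS))
    arom = np.array([1.0 if atom.GetIsAromatic() else 0.0])
    hyb = atom.GetHybridization()
    hybv = _one_hot(HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS
                    else len(HYBRIDIZATIONS), len(HYBRIDIZATIONS) + 1)
    tag = atom.GetChiralTag()
    chi = _one_hot(CHIRAL_TAGS.index(tag) if tag in CHIRAL_TAGS
                   else len(CHIRAL_TAGS), len(CHIRAL_TAGS) + 1)
    deg = _one_hot(min(atom.GetDegree(), MAX_DEGREE), MAX_DEGREE + 1)
    return np.concatenate([elem, chg, arom, hybv, chi, deg])


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    """Bond descriptor: bond-type one-hot, in-ring flag, conjugated flag."""
    bt = bond.GetBondType()
    tv = _one_hot(BOND_TYPES.index(bt) if bt in BOND_TYPES else 0, len(BOND_TYPES))
    return np.concatenate([tv, [1.0 if bond.IsInRing() else 0.0],
                           [1.0 if bond.GetIsConjugated() else 0.0]])


# ----------------------------------------------------------------------
# core containers
# ----------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Atoms + directed bond records; each chemical bond appears twice
    (i->j and j->i) with identical feature content."""

    atom_features: np.ndarray       # (n_atoms, ATOM_FEATURE_DIM)
    edge_src: np.ndarray            # (n_dir_edges,) int
    edge_dst: np.ndarray            # (n_dir_edges,) int
    bond_features: np.ndarray       # (n_dir_edges, BOND_FEATURE_DIM)
    n_atoms: int
    supernode_state: np.ndarray | None = None


@dataclass
class TokenSequence:
    """Fixed-length token-id vector; id 0 is padding."""

    token_ids: np.ndarray           # (L_s,) int
    valid_length: int


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    graph: MolecularGraph
    tokens: TokenSequence | None = None


@dataclass
class InteractionDataset:
    """Drugs + undirected positive interaction pairs + 0/1 adjacency."""

    drugs: list[DrugRecord]
    positive_pairs: set[tuple[int, int]]   # index pairs, i < j
    adjacency: np.ndarray                  # (n, n) symmetric, zero diagonal
    vocab: dict[str, int] = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def id_to_index(self) -> dict[str, int]:
        return {d.drug_id: i for i, d in enumerate(self.drugs)}

    def validate(self) -> None:
        n = self.n_drugs
        A = self.adjacency
        assert A.shape == (n, n)
        assert np.array_equal(A, A.T), "adjacency must be symmetric"
        assert not A.diagonal().any(), "adjacency must have zero diagonal"
        expected = np.zeros((n, n), dtype=A.dtype)
        for i, j in self.positive_pairs:
            expected[i, j] = expected[j, i] = 1
        assert np.array_equal(A, expected), "adjacency and pair set disagree"


@dataclass
class SplitBundle:
    """Disjoint positive partitions with matched sampled negatives."""

    train_pos: list[tuple[int, int]]
    val_pos: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]
    val_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    seed: int

    def partition(self, name: str) -> tuple[list, list]:
        return (getattr(self, f"{name}_pos"), getattr(self, f"{name}_neg"))


# ----------------------------------------------------------------------
# SMILES -> molecular graph
# ----------------------------------------------------------------------

class SmilesParseError(ValueError):
    pass


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized molecular graph.

    Atom order is RDKit's canonical order for the input string (stable for
    a fixed string).  Raises :class:`SmilesParseError` for strings RDKit
    cannot sanitize.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n < 1:
        raise SmilesParseError(f"no atoms in SMILES: {smiles!r}")
    atom_feats = np.stack([atom_feature_vector(a) for a in mol.GetAtoms()])
    src, dst, bf = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        feat = bond_feature_vector(bond)
        src += [i, j]
        dst += [j, i]
        bf += [feat, feat]
    bond_feats = (np.stack(bf) if bf
                  else np.zeros((0, BOND_FEATURE_DIM)))
    return MolecularGraph(
        atom_features=atom_feats,
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        bond_features=bond_feats,
        n_atoms=n,
    )


# ----------------------------------------------------------------------
# SMILES tokenization
# ----------------------------------------------------------------------

# bracket atoms and the two-letter organic-subset halogens are single
# tokens; every other character stands alone
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|Cl|Br|.")


def tokenize_smiles(smiles: str) -> list[str]:
    """Deterministic left-to-right SMILES tokenization."""
    if smiles.count("[") != smiles.count("]"):
        raise ValueError(f"unbalanced brackets in SMILES: {smiles!r}")
    tokens = _TOKEN_RE.findall(smiles)
    if any(t in ("[", "]") for t in tokens):
        raise ValueError(f"unbalanced brackets in SMILES: {smiles!r}")
    return tokens


def fit_vocabulary(corpus: list[list[str]]) -> dict[str, int]:
    """Assign token ids by first appearance; id 0 is reserved for padding.

    The map is order-sensitive: the same documents in a different order
    (or with tokens reordered) generally produce a different map.
    """
    if not corpus:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    vocab: dict[str, int] = {PAD_TOKEN: PAD_ID}
    for tokens in corpus:
        for t in tokens:
            if t not in vocab:
                vocab[t] = len(vocab)
    return vocab


def encode_tokens(tokens: list[str], vocab: dict[str, int],
                  unk_id: int | None = None) -> np.ndarray:
    """Map tokens to ids; unknown tokens go to `unk_id` if given, else raise."""
    ids = []
    for t in tokens:
        if t in vocab:
            ids.append(vocab[t])
        elif unk_id is not None:
            ids.append(unk_id)
        else:
            raise KeyError(f"token {t!r} not in vocabulary")
    return np.asarray(ids, dtype=np.intp)


def pad_or_cut(token_ids: np.ndarray, L_s: int) -> TokenSequence:
    """Zero-pad or tail-cut a token-id vector to fixed length L_s."""
    if L_s < 1:
        raise ValueError("L_s must be >= 1")
    token_ids = np.asarray(token_ids, dtype=np.intp)
    valid = min(len(token_ids), L_s)
    out = np.zeros(L_s, dtype=np.intp)
    out[:valid] = token_ids[:valid]
    return TokenSequence(token_ids=out, valid_length=valid)


# ----------------------------------------------------------------------
# dataset assembly and file I/O
# ----------------------------------------------------------------------

def build_dataset(records: list[tuple[str, str]],
                  pairs: list[tuple[str, str]],
                  L_s: int = 150,
                  vocab: dict[str, int] | None = None) -> InteractionDataset:
    """Assemble an :class:`InteractionDataset` from (id, SMILES) records and
    undirected positive id pairs.

    Drugs whose SMILES cannot be parsed are dropped (with a log line), as
    are edges referencing dropped drugs.  Duplicate drug ids, duplicate
    pairs and self-pairs are errors.
    """
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate drug ids: {dupes}")

    drugs: list[DrugRecord] = []
    dropped = 0
    for drug_id, smiles in records:
        try:
            graph = parse_smiles(smiles)
        except SmilesParseError as exc:
            logger.info("dropping drug %s: %s", drug_id, exc)
            dropped += 1
            continue
        drugs.append(DrugRecord(drug_id=drug_id, smiles=smiles, graph=graph))
    if dropped:
        logger.info("dropped %d drugs with unparsable SMILES", dropped)
    if not drugs:
        raise ValueError("no parsable drugs in input")

    if vocab is None:
        vocab = fit_vocabulary([tokenize_smiles(d.smiles) for d in drugs])
    unk = len(vocab)  # OOV id used only when an external vocab is supplied
    for d in drugs:
        ids_arr = encode_tokens(tokenize_smiles(d.smiles), vocab, unk_id=unk)
        d.tokens = pad_or_cut(ids_arr, L_s)

    index = {d.drug_id: i for i, d in enumerate(drugs)}
    positive: set[tuple[int, int]] = set()
    dropped_edges = 0
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-interaction edge: ({a}, {b})")
        if a not in index or b not in index:
            dropped_edges += 1
            continue
        i, j = sorted((index[a], index[b]))
        if (i, j) in positive:
            raise ValueError(f"duplicate interaction pair: ({a}, {b})")
        positive.add((i, j))
    if dropped_edges:
        logger.info("dropped %d edges referencing removed drugs", dropped_edges)

    n = len(drugs)
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in positive:
        A[i, j] = A[j, i] = 1
    ds = InteractionDataset(drugs=drugs, positive_pairs=positive,
                            adjacency=A, vocab=vocab)
    ds.validate()
    return ds


def read_dataset(drug_table_path: str | Path, edge_list_path: str | Path,
                 L_s: int = 150,
                 vocab: dict[str, int] | None = None) -> InteractionDataset:
    """Read the drug table (CSV/TSV: drug_id,smiles) and the positive edge
    list (CSV: drug_id_a,drug_id_b) and assemble the dataset."""
    drug_df = pd.read_csv(drug_table_path, sep=None, engine="python",
                          dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in drug_df.columns:
            raise ValueError(f"drug table missing column {col!r}")
    edge_df = pd.read_csv(edge_list_path, sep=None, engine="python", dtype=str)
    for col in ("drug_id_a", "drug_id_b"):
        if col not in edge_df.columns:
            raise ValueError(f"edge list missing column {col!r}")
    records = list(zip(drug_df["drug_id"], drug_df["smiles"]))
    pairs = list(zip(edge_df["drug_id_a"], edge_df["drug_id_b"]))
    return build_dataset(records, pairs, L_s=L_s, vocab=vocab)


def write_dataset(dataset: InteractionDataset, out_dir: str | Path) -> None:
    """Write drugs.csv and edges.csv in the package's file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"drug_id": [d.drug_id for d in dataset.drugs],
         "smiles": [d.smiles for d in dataset.drugs]}
    ).to_csv(out / "drugs.csv", index=False)
    rows = [(dataset.drugs[i].drug_id, dataset.drugs[j].drug_id)
            for i, j in sorted(dataset.positive_pairs)]
    pd.DataFrame(rows, columns=["drug_id_a", "drug_id_b"]).to_csv(
        out / "edges.csv", index=False)


def write_splits(dataset: InteractionDataset, splits: SplitBundle,
                 path: str | Path) -> None:
    rows = []
    for part in ("train", "val", "test"):
        pos, neg = splits.partition(part)
        for (i, j), label in itertools.chain(
                ((p, 1) for p in pos), ((p, 0) for p in neg)):
            rows.append((dataset.drugs[i].drug_id, dataset.drugs[j].drug_id,
                         label, part))
    pd.DataFrame(rows, columns=["drug_id_a", "drug_id_b", "label",
                                "partition"]).to_csv(path, index=False)


def read_splits(dataset: InteractionDataset, path: str | Path) -> SplitBundle:
    df = pd.read_csv(path, dtype={"drug_id_a": str, "drug_id_b": str})
    index = dataset.id_to_index
    parts: dict[str, dict[int, list]] = {
        p: {1: [], 0: []} for p in ("train", "val", "test")}
    for _, row in df.iterrows():
        i, j = sorted((index[row["drug_id_a"]], index[row["drug_id_b"]]))
        parts[row["partition"]][int(row["label"])].append((i, j))
    return SplitBundle(
        train_pos=parts["train"][1], val_pos=parts["val"][1],
        test_pos=parts["test"][1], train_neg=parts["train"][0],
        val_neg=parts["val"][0], test_neg=parts["test"][0], seed=-1)


# ----------------------------------------------------------------------
# transductive splits with matched negatives
# ----------------------------------------------------------------------

def make_splits(dataset: InteractionDataset, seed: int) -> SplitBundle:
    """Randomly partition positives 64/16/20 (train/val/test) and sample an
    equal number of never-positive pairs for each partition.

    Negatives are drawn without replacement across the whole bundle, so no
    negative appears twice anywhere and none ever collides with a positive.
    """
    positives = sorted(dataset.positive_pairs)
    n_pos = len(positives)
    if n_pos < 5:
        raise ValueError("need at least 5 positive pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pos)
    n_test = int(round(0.20 * n_pos))
    n_val = int(round(0.16 * n_pos))
    n_train = n_pos - n_test - n_val
    shuffled = [positives[k] for k in order]
    train_pos = shuffled[:n_train]
    val_pos = shuffled[n_train:n_train + n_val]
    test_pos = shuffled[n_train + n_val:]

    neg = sample_negative_pairs(dataset.adjacency, n_pos, rng)
    return SplitBundle(
        train_pos=train_pos, val_pos=val_pos, test_pos=test_pos,
        train_neg=neg[:n_train], val_neg=neg[n_train:n_train + n_val],
        test_neg=neg[n_train + n_val:], seed=seed)


def sample_negative_pairs(adjacency: np.ndarray, count: int,
                          rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniformly sample `count` distinct unordered non-adjacent pairs."""
    n = adjacency.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = adjacency[iu, ju] == 0
    candidates = np.stack([iu[mask], ju[mask]], axis=1)
    if len(candidates) < count:
        raise ValueError(
            f"graph too dense: only {len(candidates)} negative pairs "
            f"available, {count} required")
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return [tuple(p) for p in candidates[chosen]]


# ----------------------------------------------------------------------
# synthetic datasets: planted-partition interactions over library SMILES
# ----------------------------------------------------------------------

# Small library of drug-like and fragment SMILES used by the synthetic
# generator.  All strings are valid and parse to >= 1 heavy atom.
SMILES_LIBRARY = [
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CCO",                            # ethanol
    "c1ccccc1",                       # benzene
    "Cc1ccccc1",                      # toluene
    "c1ccc2ccccc2c1",                 # naphthalene
    "c1ccncc1",                       # pyridine
    "c1ccoc1",                        # furan
    "c1ccsc1",                        # thiophene
    "c1cc[nH]c1",                     # pyrrole
    "c1cnc[nH]1",                     # imidazole
    "C1CCCCC1",                       # cyclohexane
    "C1CCNCC1",                       # piperidine
    "C1CCOC1",                        # THF
    "C1COCCN1",                       # morpholine
    "OCC(O)CO",                       # glycerol
    "NC(=O)c1ccccc1",                 # benzamide
    "OC(=O)c1ccccc1",                 # benzoic acid
    "Nc1ccccc1",                      # aniline
    "Oc1ccccc1",                      # phenol
    "COc1ccccc1",                     # anisole
    "Clc1ccccc1",                     # chlorobenzene
    "Brc1ccccc1",                     # bromobenzene
    "Fc1ccccc1",                      # fluorobenzene
    "CC(N)C(=O)O",                    # alanine
    "NCC(=O)O",                       # glycine
    "CC(C)CC(N)C(=O)O",               # leucine
    "N[C@@H](Cc1ccccc1)C(=O)O",       # phenylalanine
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",  # melatonin
    "CN1CCC[C@H]1c1cccnc1",           # nicotine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",     # citric acid
    "C(C(=O)O)C(=O)O",                # malonic acid
    "OC(=O)C=CC(=O)O",                # fumaric acid
    "CCCCCC",                         # hexane
    "CCCCCCCC(=O)O",                  # octanoic acid
    "CCN(CC)CC",                      # triethylamine
    "CC(C)O",                         # isopropanol
    "CC(C)=O",                        # acetone
    "CCOC(=O)C",                      # ethyl acetate
    "CSC",                            # dimethyl sulfide
    "CS(=O)C",                        # DMSO
    "NC(N)=O",                        # urea
    "NC(=S)N",                        # thiourea
    "C#N",                            # hydrogen cyanide
    "CC#N",                           # acetonitrile
    "OCCO",                           # ethylene glycol
    "OCCN",                           # ethanolamine
    "NCCN",                           # ethylenediamine
    "O=C1CCCCC1",                     # cyclohexanone
    "OC1CCCCC1",                      # cyclohexanol
    "C1=CC(=O)C=CC1=O",               # quinone
    "Oc1ccc(O)cc1",                   # hydroquinone
    "Oc1ccccc1O",                     # catechol
    "OCc1ccccc1",                     # benzyl alcohol
    "O=Cc1ccccc1",                    # benzaldehyde
    "CC(=O)c1ccccc1",                 # acetophenone
    "c1ccc(-c2ccccc2)cc1",            # biphenyl
    "C=Cc1ccccc1",                    # styrene
    "N#Cc1ccccc1",                    # benzonitrile
    "O=[N+]([O-])c1ccccc1",           # nitrobenzene
    "CN(C)c1ccccc1",                  # dimethylaniline
    "Cn1ccnc1",                       # methylimidazole
    "c1ccc2[nH]ccc2c1",               # indole
    "c1ccc2ncccc2c1",                 # quinoline
    "c1ccc2ocnc2c1",                  # benzoxazole
    "c1ccc2scnc2c1",                  # benzothiazole
    "c1cnc2[nH]ccc2c1",               # azaindole
    "O=c1cc[nH]c(=O)[nH]1",           # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",          # thymine
    "Nc1ncnc2[nH]cnc12",              # adenine
    "O=c1[nH]cnc2[nH]cnc12",          # hypoxanthine
    "OCC1OC(O)C(O)C(O)C1O",           # glucose
    "CC(O)C(=O)O",                    # lactic acid
    "OC(=O)C(O)C(O)C(=O)O",           # tartaric acid
    "CCCCN",                          # butylamine
    "CCCCO",                          # butanol
    "CCOCC",                          # diethyl ether
    "ClCCl",                          # DCM
    "ClC(Cl)Cl",                      # chloroform
    "FC(F)F",                         # fluoroform
    "CC(C)(C)O",                      # tert-butanol
    "CC(C)(C)c1ccccc1",               # tert-butylbenzene
    "CCc1ccccc1",                     # ethylbenzene
    "Cc1ccccc1C",                     # xylene
    "Cc1ccc(C)cc1",                   # p-xylene
    "CNC",                            # dimethylamine
    "CN(C)C=O",                       # DMF
    "CC(=O)N(C)C",                    # DMA
    "OC(=O)CCc1ccccc1",               # hydrocinnamic acid
    "NC(=O)CCc1ccccc1",               # amide analog
    "OC(=O)C=Cc1ccccc1",              # cinnamic acid
    "COC(=O)c1ccccc1",                # methyl benzoate
    "CCOC(=O)c1ccccc1",               # ethyl benzoate
    "NS(=O)(=O)c1ccccc1",             # benzenesulfonamide
    "CS(=O)(=O)c1ccccc1",             # methyl phenyl sulfone
    "O=S(=O)(O)c1ccccc1",             # benzenesulfonic acid
    "CCCC(=O)O",                      # butyric acid
    "CC(C)C(=O)O",                    # isobutyric acid
]

# substituents prepended to a library SMILES for variety; the decorated
# string is kept only if RDKit accepts it
_SUBSTITUENTS = ["C", "CC", "CCC", "CO", "CN", "OC", "NC", "CCO", "CCN",
                 "ClC", "FC", "OCC", "C(C)C"]


def _synthetic_smiles(rng: np.random.Generator,
                      pool: list[str] | None = None,
                      used: set[str] | None = None) -> str:
    """Draw a (possibly substituent-decorated) SMILES from `pool`,
    avoiding strings in `used` when possible — a drug table should not
    list the same molecule twice."""
    pool = pool if pool is not None else SMILES_LIBRARY
    candidate = pool[rng.integers(len(pool))]
    for _ in range(30):
        base = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            decorated = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))] + base
            candidate = decorated if Chem.MolFromSmiles(decorated) else base
        else:
            candidate = base
        if used is None or candidate not in used:
            break
    if used is not None:
        used.add(candidate)
    return candidate


def generate_synthetic(n_drugs: int, n_communities: int, p_in: float,
                       p_out: float, seed: int, L_s: int = 150,
                       scaffolds_per_community: int = 2
                       ) -> InteractionDataset:
    """Generate a synthetic interaction dataset with planted communities.

    Interactions follow a planted-partition graph with within-community
    probability `p_in` and between-community probability `p_out`, so
    community membership is a learnable link signal.  Each community is
    assigned a small disjoint family of scaffold SMILES from the built-in
    library, and its drugs are (optionally substituent-decorated) variants
    of those scaffolds — mirroring real interaction data, where drug
    classes are chemically coherent and molecularly similar drugs share
    interaction partners.  Community membership is therefore learnable
    from the molecular graph and SMILES channels as well as from the
    interaction structure.  Fully reproducible under `seed`.
    """
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs")
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    community = np.array([i * n_communities // n_drugs for i in range(n_drugs)])
    k = max(1, min(scaffolds_per_community,
                   len(SMILES_LIBRARY) // n_communities))
    lib_order = rng.permutation(len(SMILES_LIBRARY))
    pools = [[SMILES_LIBRARY[j] for j in lib_order[c * k:(c + 1) * k]]
             for c in range(n_communities)]
    used: set[str] = set()
    records = [(f"D{i:04d}", _synthetic_smiles(rng, pools[community[i]], used))
               for i in range(n_drugs)]
    pairs = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            p = p_in if community[i] == community[j] else p_out
            if rng.random() < p:
                pairs.append((records[i][0], records[j][0]))
    return build_dataset(records, pairs, L_s=L_s)
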
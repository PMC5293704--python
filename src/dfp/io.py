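"""Reading and writing fingerprint collections and database fingerprints.

Two interchange formats are supported for libraries: the FPS v1 text
format (hex-encoded fingerprints, the de-facto standard for binary
fingerprint exchange) and plain CSV/TSV bit matrices.  Database
fingerprints are stored in a small package-native text format (key-value
header plus one 0/1 string) so that the threshold, strategy and source
size travel with the bits.

An optional structure adapter computes MACCS keys from SMILES or SDF
files through RDKit; it is the only place the package touches chemical
structures.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .core import DatabaseFingerprint
from .errors import CapabilityError, FormatError, InputError, ValidationError
from .schemes import BitMatrix, FingerprintScheme, MACCS166, scheme_for_length

__all__ = [
    "read_fps",
    "write_fps",
    "read_bit_csv",
    "write_bit_csv",
    "structures_to_maccs",
    "read_dfp_record",
    "write_dfp_record",
    "DFP_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

DFP_FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# FPS v1
# ---------------------------------------------------------------------------

def _hex_to_bits(hexstr: str, num_bits: int, lineno: int) -> np.ndarray:
    """Decode an FPS hex field: bit k lives in byte k>>3, mask 1<<(k&7)."""
    n_bytes = (num_bits + 7) // 8
    if len(hexstr) != 2 * n_bytes:
        raise FormatError(
            f"line {lineno}: hex field has {len(hexstr)} characters, "
            f"expected {2 * n_bytes} for num_bits={num_bits}"
        )
    try:
        raw = bytes.fromhex(hexstr)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: invalid hex field") from exc
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8), bitorder="little")
    if bits[num_bits:].any():
        raise FormatError(
            f"line {lineno}: pad bits beyond num_bits={num_bits} are set"
        )
    return bits[:num_bits]


def read_fps(path: str | Path, source_label: str | None = None) -> BitMatrix:
    """Read an FPS v1 fingerprint file into a :class:`BitMatrix`.

    The bit length is taken from the mandatory ``#num_bits=`` header
    line; 166- and 881-bit files are tagged with the MACCS166 and
    PUBCHEM881 schemes respectively, anything else is GENERIC.
    """
    path = Path(path)
    num_bits: int | None = None
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#num_bits="):
                    value = int(line.split("=", 1)[1])
                    if num_bits is not None and num_bits != value:
                        raise FormatError(
                            f"contradictory num_bits headers in {path}"
                        )
                    num_bits = value
                continue
            if num_bits is None:
                raise FormatError(f"{path}: missing #num_bits= header")
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"line {lineno}: expected '<hex>\\t<id>' record"
                )
            hexstr, mol_id = fields[0], fields[1]
            rows.append(_hex_to_bits(hexstr, num_bits, lineno))
            if mol_id in ids:
                raise ValidationError(
                    f"line {lineno}: duplicate identifier {mol_id!r}"
                )
            ids.append(mol_id)
    if num_bits is None:
        raise FormatError(f"{path}: missing #num_bits= header")
    if not rows:
        raise InputError(f"{path}: no fingerprint records")
    return BitMatrix(
        ids=ids,
        bits=np.vstack(rows),
        scheme=scheme_for_length(num_bits),
        source_label=source_label if source_label is not None else path.stem,
    )


def write_fps(matrix: BitMatrix, path: str | Path) -> None:
    """Write a :class:`BitMatrix` as an FPS v1 file (hex TAB id records)."""
    path = Path(path)
    n_bytes = (matrix.length + 7) // 8
    with path.open("w") as handle:
        handle.write("#FPS1\n")
        handle.write(f"#num_bits={matrix.length}\n")
        handle.write(f"#type=dfp/{matrix.scheme.name}\n")
        if matrix.source_label:
            handle.write(f"#source={matrix.source_label}\n")
        for mol_id, row in zip(matrix.ids, matrix.bits):
            packed = np.packbits(row, bitorder="little")
            packed = np.pad(packed, (0, n_bytes - len(packed)))
            handle.write(f"{packed.tobytes().hex()}\t{mol_id}\n")


# ---------------------------------------------------------------------------
# CSV / TSV bit matrices
# ---------------------------------------------------------------------------

def _is_bit_token(token: str) -> bool:
    return token != "" and set(token) <= {"0", "1"}


def read_bit_csv(path: str | Path, scheme: FingerprintScheme,
                 source_label: str | None = None) -> BitMatrix:
    """Read a CSV/TSV bit matrix (narrow or wide dialect).

    Narrow dialect: ``id,<L-character 0/1 string>``.  Wide dialect:
    ``id,b0,b1,...,b{L-1}``.  The delimiter (comma or tab) is detected
    from the first line; a header row is skipped if its bit fields are
    not pure 0/1 tokens.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    lines = [ln for ln in text if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    reader = list(csv.reader(lines, delimiter=delim))
    first = reader[0]
    is_header = (len(reader) > 1 and len(first) >= 2
                 and not all(_is_bit_token(t) for t in first[1:]))
    if is_header:
        reader = reader[1:]
    ids: list[str] = []
    rows: list[np.ndarray] = []
    length = scheme.length
    for rownum, record in enumerate(reader, start=1):
        if len(record) < 2:
            raise ValidationError(f"row {rownum}: expected id plus bits")
        mol_id = record[0]
        fields = record[1:]
        if len(fields) == 1 and length != 1:
            tokens = list(fields[0])
        else:
            tokens = fields
        if any(t not in ("0", "1") for t in tokens):
            raise ValidationError(
                f"row {rownum} ({mol_id}): characters outside {{0,1}}"
            )
        if len(tokens) != length:
            raise ValidationError(
                f"row {rownum} ({mol_id}): {len(tokens)} bits, expected {length}"
            )
        ids.append(mol_id)
        rows.append(np.fromiter((int(t) for t in tokens), dtype=np.uint8,
                                count=length))
    return BitMatrix(
        ids=ids,
        bits=np.vstack(rows),
        scheme=scheme,
        source_label=source_label if source_label is not None else path.stem,
    )


def write_bit_csv(matrix: BitMatrix, path: str | Path,
                  dialect: str = "narrow", delimiter: str = ",") -> None:
    """Write a bit matrix as CSV/TSV in the narrow or wide dialect."""
    if dialect not in ("narrow", "wide"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        for mol_id, row in zip(matrix.ids, matrix.bits):
            if dialect == "narrow":
                writer.writerow([mol_id, "".join(map(str, row))])
            else:
                writer.writerow([mol_id, *row.tolist()])


# ---------------------------------------------------------------------------
# Structures -> MACCS keys (optional RDKit backend)
# ---------------------------------------------------------------------------

def structures_to_maccs(path: str | Path,
                        source_label: str | None = None) -> BitMatrix:
    """Compute 166-bit MACCS keys for a SMILES (.smi) or SDF file.

    RDKit emits 167 positions with position 0 unused; that dummy
    position is dropped so key k (1..166) maps to column k-1.  Molecules
    that fail structure parsing are skipped with a logged warning.
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import MACCSkeys
    except ImportError as exc:  # pragma: no cover - backend present in CI env
        raise CapabilityError(
            "RDKit is required to compute MACCS keys from structures; "
            "install the 'chem' extra or supply precomputed FPS/CSV files"
        ) from exc
    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    mols: list[tuple[str, object]] = []
    if path.suffix.lower() in (".smi", ".smiles", ".txt"):
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"MOL_{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("skipping unparseable SMILES %r (%s)",
                               smiles, mol_id)
                continue
            mols.append((mol_id, mol))
    else:
        supplier = Chem.SDMolSupplier(str(path))
        for idx, mol in enumerate(supplier, start=1):
            if mol is None:
                logger.warning("skipping unparseable SDF record %d", idx)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            mols.append((name or f"MOL_{idx}", mol))
    if not mols:
        raise InputError(f"{path}: no parseable molecules")
    ids = []
    rows = []
    for mol_id, mol in mols:
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 positions, position 0 unused
        row = np.zeros(166, dtype=np.uint8)
        for key in fp.GetOnBits():
            if key >= 1:
                row[key - 1] = 1
        ids.append(mol_id)
        rows.append(row)
    return BitMatrix(
        ids=ids,
        bits=np.vstack(rows),
        scheme=MACCS166,
        source_label=source_label if source_label is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Native DFP record format
# ---------------------------------------------------------------------------

def write_dfp_record(dfp: DatabaseFingerprint, path: str | Path) -> None:
    """Serialize a database fingerprint with its provenance metadata."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("#DFP1\n")
        handle.write(f"#format_version={DFP_FORMAT_VERSION}\n")
        handle.write(f"#scheme={dfp.scheme.name}\n")
        handle.write(f"#num_bits={dfp.scheme.length}\n")
        handle.write(f"#threshold={dfp.threshold!r}\n")
        handle.write(f"#strategy={dfp.strategy}\n")
        handle.write(f"#n_source={dfp.n_source}\n")
        handle.write(f"#source_label={dfp.source_label}\n")
        handle.write("".join(map(str, dfp.bits)) + "\n")


def read_dfp_record(path: str | Path) -> DatabaseFingerprint:
    """Read a database fingerprint written by :func:`write_dfp_record`."""
    path = Path(path)
    header: dict[str, str] = {}
    bitstring: str | None = None
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "#DFP1":
        raise FormatError(f"{path}: not a DFP record (missing #DFP1 magic)")
    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            header[key] = value
        else:
            bitstring = line
    version = header.get("format_version")
    if version != DFP_FORMAT_VERSION:
        raise FormatError(
            f"{path}: unsupported format_version {version!r}"
        )
    if bitstring is None:
        raise FormatError(f"{path}: missing bitstring line")
    try:
        num_bits = int(header["num_bits"])
        scheme = FingerprintScheme(header["scheme"], num_bits)
        threshold = float(header["threshold"])
        n_source = int(header["n_source"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed DFP header") from exc
    if len(bitstring) != num_bits or set(bitstring) - {"0", "1"}:
        raise FormatError(
            f"{path}: bitstring must be {num_bits} characters over 0/1"
        )
    bits = np.fromiter((int(c) for c in bitstring), dtype=np.uint8,
                       count=num_bits)
    return DatabaseFingerprint(
        bits=bits,
        threshold=threshold,
        strategy=header.get("strategy", "fixed"),
        n_source=n_source,
        scheme=scheme,
        source_label=header.get("source_label", ""),
    )
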
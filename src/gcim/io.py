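"""Delimited-text readers and writers for maps, genotypes and phenotypes.

Formats (comma-delimited by default):

* map: columns ``name, chromosome, position_cM``;
* genotypes: individuals x markers, first column ``id``, symbols
  ``A``/``H``/``-`` for +1/-1/missing (configurable);
* phenotype: columns ``id, <trait>``; covariates: ``id`` plus columns.

An R/qtl-style combined CSV (phenotype columns, then marker columns with
chromosome and position header rows) is also accepted. Markers sharing a
(chromosome, position) are collapsed to the first by input order, with a
logged count.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeData, collapse_duplicate_positions

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_inputs",
    "read_cross_csv",
    "write_truth",
    "DEFAULT_SYMBOLS",
]

logger = logging.getLogger("gcim")

DEFAULT_SYMBOLS = {"A": 1.0, "H": -1.0, "-": np.nan}


def read_map(path, sep=",") -> GeneticMap:
    df = pd.read_csv(path, sep=sep)
    required = {"name", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"map file {path} must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    df["chromosome"] = df["chromosome"].astype(str)
    df = df.sort_values(
        ["chromosome", "position_cM"], kind="stable", key=_chrom_sort_key
    ).reset_index(drop=True)
    df, n_dropped = collapse_duplicate_positions(df)
    if n_dropped:
        logger.info("collapsed %d duplicate-position markers", n_dropped)
    return GeneticMap.from_frame(df)


def _chrom_sort_key(col):
    if col.name == "chromosome":
        return col.map(lambda c: (0, int(c)) if str(c).isdigit() else (1, str(c)))
    return col


def write_map(gmap: GeneticMap, path, sep=","):
    gmap.to_frame().to_csv(path, sep=sep, index=False)


def read_genotypes(path, sep=",", symbols=None) -> pd.DataFrame:
    """Genotype table indexed by individual id, columns = marker names."""
    symbols = symbols or DEFAULT_SYMBOLS
    df = pd.read_csv(path, sep=sep, dtype=str)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    bad = set()
    for col in df.columns:
        unknown = set(df[col].dropna().unique()) - set(symbols)
        bad |= unknown
    if bad:
        raise ValueError(
            f"genotype file {path} contains symbols {sorted(bad)} outside "
            f"the symbol table {symbols}"
        )
    return df.apply(lambda c: c.map(symbols)).astype(float)


def write_genotypes(geno: GenotypeData, path, sep=",", symbols=None):
    symbols = symbols or DEFAULT_SYMBOLS
    inverse = {v: k for k, v in symbols.items() if np.isfinite(v)}
    missing_symbol = next(k for k, v in symbols.items() if not np.isfinite(v))
    true_cols = ~geno.is_pseudo
    codes = geno.codes[:, true_cols]
    out = np.full(codes.shape, missing_symbol, dtype=object)
    for value, symbol in inverse.items():
        out[codes == value] = symbol
    pd.DataFrame(out, index=geno.ids, columns=geno.names[true_cols]).to_csv(
        path, sep=sep, index_label="id"
    )


def read_phenotype(path, sep=",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    return df.set_index(df.columns[0])


def write_phenotype(ids, y, path, trait="trait", sep=","):
    pd.DataFrame({"id": ids, trait: np.asarray(y)}).to_csv(path, sep=sep, index=False)


def write_truth(truth: pd.DataFrame, path, sep=","):
    truth.to_csv(path, sep=sep, index=False)


def read_cross_csv(path, n_pheno: int = 1, symbols=None):
    """Read an R/qtl-style combined CSV (rotated layout).

    Row 1 names phenotypes then markers, row 2 gives chromosomes (blank
    under phenotypes), row 3 positions; subsequent rows are individuals.
    Returns ``(gmap, geno, phenotypes)``.
    """
    symbols = symbols or DEFAULT_SYMBOLS
    raw = pd.read_csv(path, header=None, dtype=str)
    header = raw.iloc[0].tolist()
    chrom_row = raw.iloc[1].tolist()
    pos_row = raw.iloc[2].tolist()
    pheno_names = header[:n_pheno]
    marker_names = header[n_pheno:]
    chroms = [str(c) for c in chrom_row[n_pheno:]]
    positions = [float(p) for p in pos_row[n_pheno:]]
    body = raw.iloc[3:].reset_index(drop=True)
    phen = body.iloc[:, :n_pheno].astype(float)
    phen.columns = pheno_names
    phen.index = [f"ind{i:04d}" for i in range(len(body))]
    geno_df = body.iloc[:, n_pheno:]
    geno_df.columns = marker_names
    codes = geno_df.apply(lambda c: c.map(symbols)).to_numpy(dtype=float)

    df = pd.DataFrame(
        {"name": marker_names, "chromosome": chroms, "position_cM": positions}
    )
    df = df.sort_values(
        ["chromosome", "position_cM"], kind="stable", key=_chrom_sort_key
    )
    order = df.index.to_numpy()
    df = df.reset_index(drop=True)
    df, n_dropped = collapse_duplicate_positions(df)
    if n_dropped:
        logger.info("collapsed %d duplicate-position markers", n_dropped)
    name_pos = {nm: j for j, nm in enumerate(marker_names)}
    cols = [name_pos[nm] for nm in df["name"]]
    gmap = GeneticMap.from_frame(df)
    geno = GenotypeData(
        codes=codes[:, cols],
        ids=phen.index.to_numpy(dtype=object),
        names=df["name"].to_numpy(),
    )
    return gmap, geno, phen


def read_inputs(map_path, geno_path, pheno_path, covar_path=None, sep=",",
                symbols=None, trait=None):
    """Read and align the separate map/genotype/phenotype(/covariate) files.

    Individuals are aligned by id across files; individuals missing the
    phenotype are dropped with a warning; a genotype/phenotype id mismatch
    raises with the offending ids. Returns ``(gmap, geno, y, X)`` with X
    the intercept plus any covariates.
    """
    gmap = read_map(map_path, sep=sep)
    geno_df = read_genotypes(geno_path, sep=sep, symbols=symbols)
    phen = read_phenotype(pheno_path, sep=sep)
    trait = trait or phen.columns[0]
    if trait not in phen.columns:
        raise ValueError(f"trait {trait!r} not in phenotype file {pheno_path}")

    missing_geno = [i for i in phen.index if i not in geno_df.index]
    if missing_geno:
        raise ValueError(
            f"phenotyped individuals absent from genotype file: {missing_geno[:10]}"
        )
    pheno_vals = phen[trait]
    keep = pheno_vals.notna()
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} individuals with missing phenotype",
            stacklevel=2,
        )
    ids = phen.index[keep]
    y = pheno_vals[keep].to_numpy(dtype=float)

    missing_markers = [nm for nm in gmap.name if nm not in geno_df.columns]
    if missing_markers:
        raise ValueError(
            f"map markers absent from genotype file: {missing_markers[:10]}"
        )
    codes = geno_df.loc[ids, list(gmap.name)].to_numpy(dtype=float)
    geno = GenotypeData(codes=codes, ids=ids.to_numpy(dtype=object),
                        names=gmap.name)

    X = np.ones((y.size, 1))
    if covar_path is not None:
        covar = pd.read_csv(covar_path, sep=sep)
        covar = covar.set_index(covar.columns[0])
        missing_cov = [i for i in ids if i not in covar.index]
        if missing_cov:
            raise ValueError(
                f"individuals absent from covariate file: {missing_cov[:10]}"
            )
        X = np.hstack([X, covar.loc[ids].to_numpy(dtype=float)])
    return gmap, geno, y, X
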
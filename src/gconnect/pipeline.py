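"""End-to-end fit: files in, connectedness report and diagnostics out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import connectedness as cn
from . import diagnostics as dg
from .genomic import (blend_G, build_G, build_H_inverse,
                      check_genotyped_in_pedigree, read_genotypes_csv,
                      subset_A22)
from .io import RunConfig, write_diagnostics_json, write_labelled_matrix
from .mme import MMEFit, fit_mme
from .model_design import DesignMatrices, build_design
from .pedigree import build_A, build_A_inverse, read_pedigree_csv

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    fit: MMEFit
    dm: DesignMatrices
    pevmean: cn.PEVMeanMatrix
    pevmean_direct: cn.PEVMeanMatrix | None
    report: "object" = field(default=None)
    diagnostics: dg.DiagnosticsBundle | None = None
    max_deviation: float | None = None


def run_fit(config: RunConfig) -> FitResult:
    """Run the full pipeline described by a RunConfig and write its outputs.

    Fits the animal model, recovers PEVMean from the fixed-effect block
    (function 3; function 2 when CG is the only fixed effect), optionally
    also computes it directly from PEV for cross-checking, and writes the
    PEVMean matrix, pairwise report and diagnostics under ``out_dir``.
    """
    from .io import read_records_csv

    ped = read_pedigree_csv(config.pedigree)
    records = read_records_csv(config.records)
    dm = build_design(records, config.model, ped)
    y = records["y"].to_numpy(dtype=float)

    A_inv = build_A_inverse(ped)
    need_A = config.pev_direct or config.relationship == "H"
    A = build_A(ped) if need_A else None
    if config.relationship == "H":
        geno = read_genotypes_csv(config.genotypes)
        gidx = check_genotyped_in_pedigree(geno, ped)
        G = build_G(geno)
        A22 = subset_A22(A, gidx)
        Gb = blend_G(G, A22, config.blend_weight)
        K_inv = build_H_inverse(A_inv, A22, Gb, gidx)
    else:
        K_inv = A_inv

    extract = config.pev_direct and ped.n <= config.dense_pev_limit
    fit = fit_mme(dm, K_inv, config.vc, y, extract_pev_block=extract,
                  dense_limit=config.dense_pev_limit)
    logger.info("fitted MME: p1=%d p2=%d q=%d (solver: sparse LU); "
                "predicted post-solve op count %d",
                dm.p1, dm.p2, ped.n, dg.op_count(dm.p1, max(dm.p2, 0)))

    pm = cn.function3(fit.var_beta, dm, config.vc.sigma_e2)
    pm_direct = None
    max_dev = None
    if fit.pev is not None:
        pm_direct = cn.pevmean_direct(fit.pev, dm)
        max_dev = float(np.abs(pm.values - pm_direct.values).max())
        logger.info("max deviation function3 vs direct PEVMean: %.3e", max_dev)

    if config.relationship == "H" and A is not None:
        # dense K only needed for the CD prior; feasible at desk scale
        K = _dense_H(A, Gb, gidx)
    else:
        K = A
    kbar = (cn.prior_cg_variance(K, dm, config.vc.sigma_g2)
            if K is not None else None)
    report = cn.build_report(pm, fit.var_beta, dm, config.vc.sigma_e2,
                             kbar=kbar, pm_direct=pm_direct)
    bundle = dg.diagnose(fit, dm, config.vc)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labelled_matrix(pm.values, pm.cg_labels, out / "pevmean_function3.csv")
    if pm_direct is not None:
        write_labelled_matrix(pm_direct.values, pm_direct.cg_labels,
                              out / "pevmean_direct.csv")
    write_labelled_matrix(fit.var_beta.v11, dm.cg_labels, out / "var_beta1.csv")
    report.to_csv(out / "report.csv", index=False)
    write_diagnostics_json(bundle.to_dict(), out / "diagnostics.json")
    return FitResult(fit=fit, dm=dm, pevmean=pm, pevmean_direct=pm_direct,
                     report=report, diagnostics=bundle, max_deviation=max_dev)


def _dense_H(A, Gb, gidx):
    from .genomic import build_H_dense

    return build_H_dense(A, Gb, gidx)
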
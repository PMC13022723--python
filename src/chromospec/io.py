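"""Text-format readers/writers and the reproducible run pipeline.

Formats are deliberately plain:

* spectra — two delimited columns (axis, value), ``#`` comment lines, an
  ``# axis: nm|cm-1`` tag emitted by the writer; 6 significant digits;
* TAS matrices — time-explicit ASCII as used by common global-analysis
  tools: first row holds the wavelengths, first column the delays; tab or
  comma delimited (autodetected);
* TCSPC histograms — two columns (time_ns, counts).

Readers validate and refuse rather than coerce: non-numeric cells, NaN,
non-monotone or duplicated axis values and ragged rows are parse errors
that name the offending line.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .lineshapes import Spectrum
from .stark import FieldConditions, fit_simultaneous
from .synthetic import (
    BandTableRow,
    GeneratorSpec,
    STARK_PRESETS,
    gen_stark_dataset,
    gen_tas_preset,
    gen_tcspc,
)
from .tas import IRFModel, KineticScheme, TASDataset, global_fit
from .tcspc import DecayHistogram, fit_decay

__all__ = [
    "ParseError",
    "read_spectrum",
    "write_spectrum",
    "read_tas",
    "write_tas",
    "read_histogram",
    "write_histogram",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _split_line(line: str) -> list[str]:
    if "\t" in line:
        return [tok for tok in line.split("\t") if tok.strip()]
    if "," in line:
        return [tok for tok in line.split(",") if tok.strip()]
    return line.split()


def _parse_float(tok: str, path, lineno: int) -> float:
    try:
        v = float(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric value {tok!r}") from None
    if not np.isfinite(v):
        raise ParseError(f"{path}:{lineno}: non-finite value {tok!r}")
    return v


def read_spectrum(path, convention: str | None = None) -> Spectrum:
    """Read a two-column spectrum; '#' comments allowed, header optional.

    The axis convention comes from an ``# axis:`` comment, a header token
    containing 'nm' / 'cm', the ``convention`` argument, or defaults to nm.
    """
    path = Path(path)
    axis: list[float] = []
    values: list[float] = []
    label = ""
    file_convention = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("axis:"):
                tag = body.split(":", 1)[1].strip()
                file_convention = "nm" if tag == "nm" else "cm-1"
            elif body.lower().startswith("label:"):
                label = body.split(":", 1)[1].strip()
            continue
        toks = _split_line(line)
        if len(toks) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(toks)}")
        try:
            x = _parse_float(toks[0], path, lineno)
        except ParseError:
            if not axis:  # tolerate one non-numeric header row
                low = line.lower()
                if file_convention is None:
                    if "cm" in low:
                        file_convention = "cm-1"
                    elif "nm" in low:
                        file_convention = "nm"
                continue
            raise
        y = _parse_float(toks[1], path, lineno)
        if axis and x == axis[-1]:
            raise ParseError(f"{path}:{lineno}: duplicated axis value {x!r}")
        axis.append(x)
        values.append(y)
    if not axis:
        raise ParseError(f"{path}: no data rows")
    conv = convention or file_convention or "nm"
    try:
        return Spectrum(np.asarray(axis), np.asarray(values), conv, label)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectrum(path, spectrum: Spectrum) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# chromospec spectrum\n")
        fh.write(f"# axis: {spectrum.convention}\n")
        if spectrum.label:
            fh.write(f"# label: {spectrum.label}\n")
        for x, y in zip(spectrum.axis, spectrum.values):
            fh.write(f"{x:.6g}\t{y:.6g}\n")


def read_tas(path) -> TASDataset:
    """Read a time-explicit TAS matrix (row 1 wavelengths, column 1 delays)."""
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append((lineno, _split_line(line)))
    if len(rows) < 2:
        raise ParseError(f"{path}: need a wavelength header row and data rows")
    lineno0, header = rows[0]
    # the corner cell (0 / label) is optional
    n_data_cols = len(rows[1][1]) - 1
    if len(header) == n_data_cols + 1:
        header = header[1:]
    wavelengths = [_parse_float(t, path, lineno0) for t in header]
    if any(w <= 0 for w in wavelengths) or any(
        b <= a for a, b in zip(wavelengths, wavelengths[1:])
    ):
        raise ParseError(
            f"{path}:{lineno0}: first row must be strictly ascending positive "
            "wavelengths; this file may be transposed (delays in the first row)"
        )
    delays, matrix = [], []
    for lineno, toks in rows[1:]:
        if len(toks) != len(wavelengths) + 1:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(toks)} columns, "
                f"expected {len(wavelengths) + 1})"
            )
        delays.append(_parse_float(toks[0], path, lineno))
        matrix.append([float(t) if t.lower() == "nan" else _parse_float(t, path, lineno)
                       for t in toks[1:]])
    try:
        return TASDataset(np.asarray(delays), np.asarray(wavelengths), np.asarray(matrix))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_tas(path, data: TASDataset, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["0"] + [f"{w:.6g}" for w in data.wavelengths]) + "\n")
        for t, row in zip(data.delays, data.deltaA):
            cells = [f"{t:.6g}"] + [
                "nan" if not np.isfinite(v) else f"{v:.8g}" for v in row
            ]
            fh.write(delimiter.join(cells) + "\n")


def read_histogram(path) -> DecayHistogram:
    spec = read_spectrum(path, convention="nm")  # reuse the 2-column parser
    try:
        return DecayHistogram(spec.axis, spec.values, spec.label)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_histogram(path, hist: DecayHistogram) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# chromospec histogram (time_ns, counts)\n")
        if hist.label:
            fh.write(f"# label: {hist.label}\n")
        # times at 10 significant digits so uniform binning survives re-reading
        for t, c in zip(hist.times, hist.counts):
            fh.write(f"{t:.10g}\t{c:.10g}\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """One reproducible command invocation.

    The exact config (command, inputs, options, seed) is written to
    ``run_config.json`` in the output directory so any run can be replayed.
    """

    command: str
    inputs: dict[str, str] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "out"
    verbose: bool = False


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def _field_from_options(opt: dict) -> FieldConditions:
    kwargs = {}
    if "field_v_per_cm" in opt:
        kwargs["applied_field"] = float(opt["field_v_per_cm"])
    if "field_factor" in opt:
        kwargs["field_factor"] = float(opt["field_factor"])
    if "angle_deg" in opt:
        kwargs["angle_deg"] = float(opt["angle_deg"])
    return FieldConditions(**kwargs)


def _log(cfg: RunConfig, msg: str) -> None:
    if cfg.verbose:
        print(msg, file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> int:
    """Execute one command; returns a shell-style exit status.

    Inputs are checked before any output is written, so a failed run leaves
    no partial artifacts.  Non-convergence of any fit is an error status.
    """
    for name, p in cfg.inputs.items():
        if not Path(p).is_file():
            print(f"error: input {name} not found: {p}", file=sys.stderr)
            return 2
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opt = cfg.options
    status = 0

    if cfg.command == "simulate-stark":
        preset = opt.get("preset", "2H2A")
        if preset not in STARK_PRESETS:
            print(f"error: unknown preset {preset!r}", file=sys.stderr)
            return 2
        spec = GeneratorSpec(seed=cfg.seed, noise_level=float(opt.get("noise", 0.01)))
        absorption, stark = gen_stark_dataset(
            STARK_PRESETS[preset], _field_from_options(opt), spec
        )
        write_spectrum(outdir / "absorption.tsv", absorption)
        write_spectrum(outdir / "stark.tsv", stark)
    elif cfg.command == "fit-stark":
        absorption = read_spectrum(cfg.inputs["absorption"])
        stark = read_spectrum(cfg.inputs["stark"])
        init_rows = [
            BandTableRow(
                float(r["center_nm"]), float(r["area"]), float(r["width"]),
                float(r.get("tr_dalpha", 0.0)), float(r.get("dmu", 0.0)),
            )
            for r in opt["bands"]
        ]
        result = fit_simultaneous(
            absorption,
            stark,
            _field_from_options(opt),
            [r.band() for r in init_rows],
            init_molecular=[r.molecular() for r in init_rows],
            weights=tuple(opt.get("weights", (1.0, 1.0))),
        )
        with (outdir / "parameters.tsv").open("w") as fh:
            fh.write("center_nm\tarea\twidth\ttr_dalpha_A3\tdmu_D\tphysical\n")
            for band, mol in zip(result.bands, result.molecular):
                fh.write(
                    f"{1e7 / band.center:.6g}\t{band.area:.6g}\t{band.width:.6g}"
                    f"\t{mol.tr_dalpha:.6g}\t{mol.dmu:.6g}\t{int(mol.physical)}\n"
                )
        write_spectrum(outdir / "absorption_model.tsv", result.absorption_model)
        write_spectrum(outdir / "stark_model.tsv", result.stark_model)
        if not result.converged:
            print("error: simultaneous fit did not converge", file=sys.stderr)
            status = 1
    elif cfg.command == "simulate-tas":
        spec = GeneratorSpec(seed=cfg.seed, noise_level=float(opt.get("noise", 0.01)))
        try:
            data, scheme = gen_tas_preset(opt.get("preset", "monomer"), spec=spec)
        except ValueError as exc:
            print(f"error: {exc}", file=sys.stderr)
            return 2
        write_tas(outdir / "tas.tsv", data)
        (outdir / "truth.json").write_text(
            json.dumps({"kind": scheme.kind, "lifetimes_ps": list(scheme.lifetimes)})
        )
    elif cfg.command == "fit-tas":
        data = read_tas(cfg.inputs["data"])
        lifetimes = [float(v) for v in opt["init_lifetimes_ps"]]
        fixed = [bool(v) for v in opt.get("fixed", [False] * len(lifetimes))]
        scheme = KineticScheme(opt.get("model", "sequential"), tuple(lifetimes), tuple(fixed))
        irf = IRFModel(
            t0=float(opt.get("t0", 0.0)), fwhm=float(opt.get("irf_fwhm_ps", 0.08))
        )
        result = global_fit(data, scheme, irf)
        with (outdir / "lifetimes.tsv").open("w") as fh:
            fh.write("lifetime_ps\tfixed\n")
            for tau, fx in zip(result.scheme.lifetimes, result.scheme.fixed):
                fh.write(f"{tau:.6g}\t{int(fx)}\n")
        header = "\t".join(f"{w:.6g}" for w in data.wavelengths)
        np.savetxt(outdir / "EADS.tsv", result.eads, delimiter="\t", header=header)
        np.savetxt(outdir / "DADS.tsv", result.dads, delimiter="\t", header=header)
        write_tas(
            outdir / "residual.tsv",
            TASDataset(data.delays, data.wavelengths, result.residual),
        )
        if not result.converged:
            print("error: global fit did not converge", file=sys.stderr)
            status = 1
    elif cfg.command == "simulate-tcspc":
        spec = GeneratorSpec(seed=cfg.seed)
        decay, irf = gen_tcspc(
            lifetimes=[float(v) for v in opt.get("lifetimes_ns", [3.7])],
            amplitudes=[1.0] * len(opt.get("lifetimes_ns", [3.7])),
            spec=spec,
        )
        write_histogram(outdir / "decay.tsv", decay)
        write_histogram(outdir / "irf.tsv", irf)
    elif cfg.command == "fit-tcspc":
        decay = read_histogram(cfg.inputs["decay"])
        irf = read_histogram(cfg.inputs["irf"])
        fit = fit_decay(decay, irf, n_exp=int(opt.get("n_exp", 1)))
        (outdir / "fit.json").write_text(
            json.dumps(
                {
                    "lifetimes_ns": [float(v) for v in fit.lifetimes],
                    "amplitudes": [float(v) for v in fit.amplitudes],
                    "irf_shift_ns": fit.shift,
                    "chi2_reduced": fit.chi2_reduced,
                    "passed": fit.passed,
                },
                indent=2,
            )
        )
        if not fit.converged:
            print("error: reconvolution fit did not converge", file=sys.stderr)
            status = 1
    else:
        print(f"error: unknown command {cfg.command!r}", file=sys.stderr)
        return 2

    record = {
        "command": cfg.command,
        "inputs": cfg.inputs,
        "options": {k: v for k, v in opt.items()},
        "seed": cfg.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    (outdir / "run_config.json").write_text(json.dumps(record, indent=2, default=str))
    _log(cfg, f"{cfg.command}: wrote outputs to {outdir} (status {status})")
    return status
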
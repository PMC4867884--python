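"""Event grammar, file formats, and the ``kseg`` command-line interface.

Conventions: positions and states are 1-based inclusive everywhere inside the
package; BED-like output converts to 0-based half-open at the boundary.
Models are JSON ({M, pi0, A, emission_family, emission_params}) and round-trip
bit-exactly; observations are plain text, one value per line, with optional
``#`` header lines; probability tables carry natural-log and log10 columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys

import click
import numpy as np
import yaml

from . import __version__
from .counting import CountingSpec
from .hmm_core import (
    HMMParams,
    InfeasibleEventError,
    InputError,
    KsegmentError,
    Segmentation,
    em_fit,
    viterbi,
)
from .kseg import (
    PosteriorSegmentDistribution,
    SegmentEvent,
    kseg_forward,
    kseg_sample,
    kseg_summary,
    kseg_viterbi,
)
from .learn import PriorSpec, constrained_em, constrained_gibbs
from .evalsim import IntervalPair, SimulationDesign, detection_rate, overlap_ratio, simulate_from_model

logger = logging.getLogger("ksegment")

__all__ = [
    "parse_event",
    "format_event",
    "read_model",
    "write_model",
    "read_observations",
    "write_observations",
    "read_counting_spec",
    "write_segments",
    "write_probs",
    "main",
]


# ---------------------------------------------------------------------------
# event grammar: c=K | c<=K | c>K | K1<=c<=K2
# ---------------------------------------------------------------------------


def parse_event(text: str) -> SegmentEvent:
    """Parse an event string; rejects anything outside the grammar above."""
    import re

    if not text:
        raise InputError("empty event string")
    s = text.replace(" ", "")
    m = re.fullmatch(r"c=(\d+)", s)
    if m:
        return SegmentEvent.exactly(int(m.group(1)))
    m = re.fullmatch(r"c<=(\d+)", s)
    if m:
        return SegmentEvent.at_most(int(m.group(1)))
    m = re.fullmatch(r"c>(\d+)", s)
    if m:
        return SegmentEvent.greater_than(int(m.group(1)))
    m = re.fullmatch(r"(\d+)<=c<=(\d+)", s)
    if m:
        return SegmentEvent.between(int(m.group(1)), int(m.group(2)))
    # locate the first position where no grammar rule can continue
    pos = 0
    for pref in ("c<=", "c=", "c>"):
        if s.startswith(pref[: len(s)]):
            pos = max(pos, len(pref))
    raise InputError(
        f"cannot parse event {text!r} (near position {min(pos, len(s))}): "
        "expected c=K, c<=K, c>K or K1<=c<=K2"
    )


def format_event(event: SegmentEvent) -> str:
    return str(event)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_model(path) -> HMMParams:
    with open(path) as fh:
        try:
            return HMMParams.from_dict(json.load(fh))
        except json.JSONDecodeError as e:
            raise InputError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e


def write_model(model: HMMParams, path):
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_observations(path) -> np.ndarray:
    """One value per line; lines starting with '#' are skipped."""
    values = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line.split("\t")[0]))
            except ValueError as e:
                raise InputError(f"{path}:{ln}: not a number: {line!r}") from e
    if not values:
        raise InputError(f"{path}: no observations")
    arr = np.asarray(values)
    if np.all(arr == arr.astype(int)):
        as_int = arr.astype(int)
        if np.array_equal(as_int, arr):
            return arr
    return arr


def write_observations(y, path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for v in np.asarray(y).ravel():
            v = float(v)
            fh.write(f"{int(v)}\n" if v.is_integer() else f"{v!r}\n")


def read_counting_spec(path) -> CountingSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise InputError(f"{path}: counting spec must be a mapping")
    return CountingSpec.from_dict(d)


def write_segments(path_or_seg, out, seqname: str = "seq"):
    """BED-like TSV (seqname, start, end, state), 0-based half-open."""
    seg = (
        path_or_seg
        if isinstance(path_or_seg, Segmentation)
        else Segmentation.from_path(path_or_seg)
    )
    with open(out, "w") as fh:
        fh.write("#seqname\tstart\tend\tstate\n")
        for name, start, end, state in seg.to_bed(seqname):
            fh.write(f"{name}\t{start}\t{end}\t{state}\n")


def write_path_tsv(x, out):
    with open(out, "w") as fh:
        fh.write("#index\tstate\n")
        for n, s in enumerate(np.asarray(x), start=1):
            fh.write(f"{n}\t{int(s)}\n")


def write_probs(dist: PosteriorSegmentDistribution, out):
    with open(out, "w") as fh:
        fh.write("#k\tp\tlog_p\tlog10_p\n")
        for k, p, lp in zip(dist.ks, dist.probs, dist.log_probs):
            fh.write(f"{k}\t{float(p)!r}\t{float(lp)!r}\t{float(lp) / np.log(10)!r}\n")
        fh.write(f">{dist.k_max}\t{float(dist.tail)!r}\t{float(dist.log_tail)!r}"
                 f"\t{float(dist.log_tail) / np.log(10)!r}\n")


def _config_hash(params: dict) -> str:
    blob = json.dumps({k: str(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_spec(counting) -> CountingSpec:
    return read_counting_spec(counting) if counting else CountingSpec()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _cli_errors(fn):
    import functools

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except InfeasibleEventError as e:
            click.echo(f"infeasible event: {e}", err=True)
            sys.exit(3)
        except (KsegmentError, FileNotFoundError, OSError) as e:
            click.echo(f"error: {e}", err=True)
            sys.exit(2)

    return wrapper


def _log_run(command: str, seed, params: dict):
    logger.info(
        "kseg %s | version=%s seed=%s config=%s",
        command, __version__, seed, _config_hash(params),
    )


@click.group()
@click.option("--config", type=click.Path(exists=True), default=None,
              help="YAML file mapping subcommand -> option values, used as "
                   "defaults for any option not given on the command line")
@click.option("-v", "--verbose", count=True, help="-v info, -vv debug")
@click.version_option(__version__)
@click.pass_context
def main(ctx, config, verbose):
    """Exact k-segment inference for hidden Markov models."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(level=level, format="%(levelname)s %(message)s")
    if config:
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise click.UsageError(f"{config}: config must be a mapping")
        ctx.default_map = loaded


@main.command()
@click.option("--model", type=click.Path(exists=True), default=None,
              help="simulate from this model JSON instead of the default design")
@click.option("--n", "n", type=int, default=1000, show_default=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True, help="observations TSV")
@click.option("--truth", type=click.Path(), default=None, help="true path TSV")
@_cli_errors
def simulate(model, n, seed, out, truth):
    """Simulate observations (default: the 3-state Gaussian benchmark design)."""
    _log_run("simulate", seed, locals())
    hmm = read_model(model) if model else SimulationDesign(N=n).model()
    x, y = simulate_from_model(hmm, n, seed)
    write_observations(y, out, header=f"simulated n={n} seed={seed}")
    if truth:
        write_path_tsv(x, truth)


@main.command()
@click.option("--model", type=click.Path(exists=True), required=True)
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--event", required=True, help='e.g. "c=7"')
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True, help="BED-like segments")
@_cli_errors
def decode(model, obs, event, counting, out):
    """MAP path under a segment-count event."""
    _log_run("decode", None, locals())
    path, score = kseg_viterbi(
        read_model(model), read_observations(obs), _load_spec(counting),
        parse_event(event),
    )
    write_segments(path, out)
    click.echo(f"log score\t{float(score)!r}")


@main.command()
@click.option("--model", type=click.Path(exists=True), required=True)
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--kmax", type=int, default=10, show_default=True)
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True,
              help="TSV of segments for every k (column k; absorbing entry k='>kmax')")
@_cli_errors
def summary(model, obs, kmax, counting, out):
    """k_max + 1 summary: MAP paths for c = k_min..k_max plus c > k_max."""
    _log_run("summary", None, locals())
    res = kseg_summary(
        read_model(model), read_observations(obs), _load_spec(counting), kmax
    )
    with open(out, "w") as fh:
        fh.write("#k\tstart\tend\tstate\tlog_score\n")
        for k, path, score in res.entries():
            if path is None:
                fh.write(f"{k}\t.\t.\t.\t-inf\n")
                continue
            for _, s, e, st in Segmentation.from_path(path).to_bed():
                fh.write(f"{k}\t{s}\t{e}\t{st}\t{float(score)!r}\n")
        if res.absorbing_path is not None:
            for _, s, e, st in Segmentation.from_path(res.absorbing_path).to_bed():
                fh.write(f">{res.k_max}\t{s}\t{e}\t{st}\t{float(res.absorbing_score)!r}\n")


@main.command()
@click.option("--model", type=click.Path(exists=True), required=True)
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--kmax", type=int, default=50, show_default=True)
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True, help="TSV (k, p, log_p, log10_p)")
@_cli_errors
def probs(model, obs, kmax, counting, out):
    """Exact posterior over the segment count."""
    _log_run("probs", None, locals())
    y = read_observations(obs)
    kmax = min(kmax, y.shape[0])
    dist = kseg_forward(read_model(model), y, _load_spec(counting), kmax)
    write_probs(dist, out)


@main.command()
@click.option("--model", type=click.Path(exists=True), required=True)
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--event", required=True)
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("-n", "n_samples", type=int, default=10, show_default=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True,
              help="TSV, one sampled path per row")
@_cli_errors
def sample(model, obs, event, counting, n_samples, seed, out):
    """Sample paths from the event-conditioned posterior."""
    _log_run("sample", seed, locals())
    draws = kseg_sample(
        read_model(model), read_observations(obs), _load_spec(counting),
        parse_event(event), n_samples, seed,
    )
    np.savetxt(out, draws, fmt="%d", delimiter="\t",
               header="one path per row, states 1..M")


@main.command()
@click.option("--model", "init_model", type=click.Path(exists=True), required=True,
              help="initialization model JSON")
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--constraint", default=None, help='e.g. "c<=5"; omit for unconstrained EM')
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("--tol", type=float, default=1e-6, show_default=True)
@click.option("--max-iter", type=int, default=500, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="fitted model JSON")
@click.option("--trace", type=click.Path(), default=None, help="log-likelihood trace TSV")
@_cli_errors
def fit(init_model, obs, constraint, counting, tol, max_iter, out, trace):
    """Fit parameters by (optionally k-segment-constrained) EM."""
    _log_run("fit", None, locals())
    init = read_model(init_model)
    y = read_observations(obs)
    if constraint:
        res = constrained_em(
            init, y, _load_spec(counting), parse_event(constraint),
            tol=tol, max_iter=max_iter,
        )
        fitted, tr = res.model, res.trace
    else:
        fitted, tr = em_fit(init, y, tol=tol, max_iter=max_iter)
    write_model(fitted, out)
    if trace:
        with open(trace, "w") as fh:
            fh.write("#iter\tloglik\n")
            for i, ll in enumerate(tr):
                fh.write(f"{i}\t{float(ll)!r}\n")
    click.echo(f"final log-likelihood\t{float(tr[-1])!r}")


@main.command()
@click.option("--model", "init_model", type=click.Path(exists=True), required=True)
@click.option("--obs", type=click.Path(exists=True), required=True)
@click.option("--event", required=True)
@click.option("--counting", type=click.Path(exists=True), default=None)
@click.option("--n-iter", type=int, default=100, show_default=True)
@click.option("--burn-in", type=int, default=0, show_default=True)
@click.option("--seed", type=int, required=True)
@click.option("--prefix", type=click.Path(), required=True,
              help="output prefix: <prefix>.paths.tsv, <prefix>.params.jsonl")
@_cli_errors
def gibbs(init_model, obs, event, counting, n_iter, burn_in, seed, prefix):
    """Constrained Gibbs sampling of parameters and paths."""
    _log_run("gibbs", seed, locals())
    res = constrained_gibbs(
        read_observations(obs), PriorSpec(), _load_spec(counting),
        parse_event(event), n_iter, seed, init=read_model(init_model),
        burn_in=burn_in,
    )
    np.savetxt(f"{prefix}.paths.tsv", res.paths, fmt="%d", delimiter="\t")
    with open(f"{prefix}.params.jsonl", "w") as fh:
        for m in res.models:
            fh.write(m.to_json(sort_keys=True) + "\n")


@main.command("eval-detection")
@click.option("--predicted", type=click.Path(exists=True), required=True,
              help="BED-like TSV of predicted segments")
@click.option("--truth", type=click.Path(exists=True), required=True,
              help="BED-like TSV of ground-truth segments")
@click.option("-k", type=int, required=True, help="requested list size")
@click.option("--threshold", type=float, default=0.8, show_default=True)
@_cli_errors
def eval_detection(predicted, truth, k, threshold):
    """Per-document detection rate of predicted vs ground-truth segments."""
    _log_run("eval-detection", None, locals())

    def read_bed(path):
        out = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split("\t")
                out.append((int(parts[1]) + 1, int(parts[2])))  # to 1-based inclusive
        return out

    preds, gts = read_bed(predicted), read_bed(truth)
    ratios = [
        max((overlap_ratio(IntervalPair(p, g)) for g in gts), default=0.0)
        for p in preds
    ]
    rate = detection_rate(ratios, k, threshold)
    click.echo(f"detection rate\t{float(rate)!r}")


if __name__ == "__main__":
    main()
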
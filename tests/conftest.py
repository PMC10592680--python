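import numpy as np
import pytest

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_vcf(tmp_path):
    """Factory writing a toy VCF from (pos, ref, alt, info, genotypes) rows."""

    counter = {"n": 0}

    def _make(rows, n_samples):
        counter["n"] += 1
        path = tmp_path / f"toy{counter['n']}.vcf"
        names = "\t".join(f"S{i}" for i in range(n_samples))
        lines = [VCF_HEADER.rstrip(),
                 f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}"]
        for pos, ref, alt, info, gts in rows:
            gt_cols = "\t".join(gts)
            lines.append(f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gt_cols}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _make


@pytest.fixture
def write_config(tmp_path):
    """Factory writing an INI pipeline config from a nested dict."""

    def _write(sections, name="config.ini"):
        path = tmp_path / name
        out = []
        for section, kv in sections.items():
            out.append(f"[{section}]")
            out.extend(f"{k} = {v}" for k, v in kv.items())
        path.write_text("\n".join(out) + "\n")
        return path

    return _write
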
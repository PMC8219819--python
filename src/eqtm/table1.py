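"""Packaged reference correlation table for MOBP and HIP1 CpGs.

The published analysis correlated cerebellar white-matter DNA methylation
(M-values) with cognate-gene expression in 14 MSA cases and 10 controls and
reported, per CpG, Pearson r and p in three strata: pooled (MSA + CTRL), MSA
only and CTRL only. The 23 CpGs with at least one significant correlation
(6 in MOBP, 17 in HIP1) are embedded here verbatim so report generation and
tests need no external files. p-values are stored exactly as printed
(scientific-notation strings) and parsed to floats on access.
"""

from __future__ import annotations

from .core import CorrelationRecord, ProbeAnnotation, _parse_feature_cgi

__all__ = ["table1_fixture", "TABLE1_GROUP_LABELS"]

#: Stratum labels used by the fixture records, in (group1, group2) order.
TABLE1_GROUP_LABELS = ("MSA", "CTRL")

_N_POOLED, _N_MSA, _N_CTRL = 24, 14, 10

# gene, probe, chr, mapinfo, feature-CGI, pooled r/p, MSA r/p, CTRL r/p
_TABLE1 = """\
MOBP	cg27103603	3	39544721	Body-shore	-0.513	1.0E-02	-0.716	4.0E-03	0.125	7.3E-01
MOBP	cg16959486	3	39563230	Body-opensea	-0.452	2.6E-02	-0.405	1.5E-01	-0.360	3.1E-01
MOBP	cg01684805	3	39508348	TSS1500-opensea	-0.451	2.7E-02	-0.291	3.1E-01	-0.266	4.6E-01
MOBP	cg21827971	3	39542480	TSS1500-shore	-0.440	3.1E-02	-0.509	6.3E-02	0.225	5.3E-01
MOBP	cg22110662	3	39542841	TSS1500-shore	-0.435	3.4E-02	-0.594	2.5E-02	0.281	4.3E-01
MOBP	cg05317077	3	39542991	TSS1500-shore	-0.411	4.6E-02	-0.264	3.6E-01	0.190	6.0E-01
HIP1	cg10139739	7	75280150	Body-opensea	0.539	6.6E-03	0.782	9.4E-04	-0.368	2.9E-01
HIP1	cg14796107	7	75192547	Body-shelf	0.532	7.5E-03	0.319	2.7E-01	0.719	1.9E-02
HIP1	cg01621268	7	75272341	Body-shelf	0.529	7.8E-03	0.356	2.1E-01	0.646	4.4E-02
HIP1	cg00361176	7	75260791	Body-opensea	0.437	3.3E-02	-0.042	8.9E-01	0.587	7.4E-02
HIP1	cg03370878	7	75185075	Body-shelf	-0.327	1.2E-01	-0.745	2.2E-03	0.000	1.0E+00
HIP1	cg11778783	7	75276901	Body-opensea	-0.036	8.7E-01	-0.718	3.8E-03	0.074	8.4E-01
HIP1	cg17623869	7	75251045	Body-opensea	0.047	8.3E-01	-0.703	5.0E-03	0.463	1.8E-01
HIP1	cg11416840	7	75250896	Body-opensea	-0.303	1.5E-01	-0.689	6.4E-03	-0.078	8.3E-01
HIP1	cg27409251	7	75223159	Body-opensea	0.008	9.7E-01	-0.686	6.8E-03	0.610	6.1E-02
HIP1	cg02229461	7	75185674	Body-shelf	0.031	8.9E-01	-0.614	1.9E-02	0.365	3.0E-01
HIP1	cg05421036	7	75202434	Body-opensea	0.067	7.6E-01	-0.541	4.6E-02	0.629	5.1E-02
HIP1	cg01120324	7	75249065	Body-opensea	0.262	2.2E-01	0.229	4.3E-01	0.852	1.8E-03
HIP1	cg05145297	7	75264568	Body-shelf	0.229	2.8E-01	-0.420	1.4E-01	0.772	8.9E-03
HIP1	cg26596975	7	75189250	Body-island	0.192	3.7E-01	0.018	9.5E-01	0.732	1.6E-02
HIP1	cg03437706	7	75266692	Body-shore	0.111	6.0E-01	-0.486	7.8E-02	0.722	1.8E-02
HIP1	cg14706940	7	75205521	Body-opensea	0.346	9.8E-02	-0.014	9.6E-01	0.672	3.3E-02
HIP1	cg02713883	7	75188876	Body-shore	0.253	2.3E-01	0.240	4.1E-01	0.660	3.8E-02
"""


def table1_fixture() -> tuple[list[ProbeAnnotation], list[CorrelationRecord]]:
    """Return the embedded reference table as annotations plus correlation
    records (three records per CpG: POOLED, MSA, CTRL)."""
    annotations: list[ProbeAnnotation] = []
    records: list[CorrelationRecord] = []
    for line in _TABLE1.strip().splitlines():
        gene, probe, chrom, pos, feat_cgi, rp, pp, rm, pm, rc, pc = line.split("\t")
        feature, cgi = _parse_feature_cgi(feat_cgi)
        annotations.append(
            ProbeAnnotation(
                probe_id=probe,
                chromosome=chrom,
                position=int(pos),
                gene=gene,
                feature=feature,
                cgi_relation=cgi,
            )
        )
        for stratum, r, p, n in (
            ("POOLED", rp, pp, _N_POOLED),
            ("MSA", rm, pm, _N_MSA),
            ("CTRL", rc, pc, _N_CTRL),
        ):
            records.append(
                CorrelationRecord(
                    probe_id=probe,
                    gene=gene,
                    stratum=stratum,
                    r=float(r),
                    p=float(p),
                    n=n,
                )
            )
    return annotations, records
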
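# Per-residue physicochemical property table (editable data, not code).
# Columns and provenance:
#   rigidity        curated side-chain conformational rigidity scale (ring
#                   content / branching near C-beta; proline highest, glycine
#                   lowest); unitless, package-curated
#   flexibility     average flexibility index (Bhaskaran & Ponnuswamy 1988)
#   irreplaceability  100 / Dayhoff relative mutability (Dayhoff et al. 1978);
#                   low mutability = high irreplaceability
#   hydrophobicity  Kyte & Doolittle (1982) hydropathy
#   hydrophilicity  Hopp & Woods (1981)
#   mass            average residue mass, Da
#   pk1             alpha-carboxyl pKa
#   pk2             alpha-amino pKa
#   pi              isoelectric point
# All properties are min-max scaled over the 20 residues before encoding,
# so only the ordering and relative spacing matter downstream.
residue	rigidity	flexibility	irreplaceability	hydrophobicity	hydrophilicity	mass	pk1	pk2	pi
A	0.50	0.357	1.00	1.8	-0.5	71.08	2.34	9.69	6.00
C	0.60	0.346	5.00	2.5	-1.0	103.14	1.96	10.28	5.07
D	0.37	0.511	0.94	-3.5	3.0	115.09	1.88	9.60	2.77
E	0.32	0.497	0.98	-3.5	3.0	129.12	2.19	9.67	3.22
F	0.75	0.314	2.44	2.8	-2.5	147.18	1.83	9.13	5.48
G	0.25	0.544	2.04	-0.4	0.0	57.05	2.34	9.60	5.97
H	0.68	0.323	1.52	-3.2	-0.5	137.14	1.82	9.17	7.59
I	0.62	0.462	1.04	4.5	-1.8	113.16	2.36	9.68	6.02
K	0.28	0.466	1.79	-3.9	3.0	128.17	2.18	8.95	9.74
L	0.55	0.365	2.50	3.8	-1.8	113.16	2.36	9.60	5.98
M	0.45	0.295	1.06	1.9	-1.3	131.19	2.28	9.21	5.74
N	0.35	0.463	0.75	-3.5	0.2	114.10	2.02	8.80	5.41
P	0.95	0.509	1.79	-1.6	0.0	97.12	1.99	10.60	6.30
Q	0.31	0.493	1.08	-3.5	0.2	128.13	2.17	9.13	5.65
R	0.30	0.529	1.54	-4.5	3.0	156.19	2.17	9.04	10.76
S	0.42	0.507	0.83	-0.8	0.3	87.08	2.21	9.15	5.68
T	0.48	0.444	1.03	-0.7	-0.4	101.10	2.09	9.10	5.60
V	0.60	0.386	1.35	4.2	-1.5	99.13	2.32	9.62	5.96
W	0.84	0.305	5.56	-0.9	-3.4	186.21	2.83	9.39	5.89
Y	0.78	0.420	2.44	-1.3	-2.3	163.18	2.20	9.11	5.66
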
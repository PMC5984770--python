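# Hydrogen-bond occupancy summary for the A. niger PhyA phytase (AnP, wt)
# and its 18-substitution variant AnP-M1 (mut), from 50-ns simulations at
# 50C and 70C.  Pairs are author residue numbers in chain A; occupancy is
# the fraction of frames with >= 1 bond, mean_count the average number of
# simultaneous bonds.  provenance=text marks values printed in the
# published summary narrative; provenance=figure marks values read off
# bar charts and encoded so each comparison resolves the same way the
# narrative resolves it.
variant	temperature	res_a	res_b	occupancy	mean_count	provenance
wt	50C	33	35	0.36	0.36	text
wt	70C	33	35	0.33	0.33	text
mut	50C	33	35	0.20	0.20	figure
mut	70C	33	35	0.15	0.15	figure
wt	50C	36	37	0.42	0.42	text
wt	70C	36	37	0.40	0.40	text
mut	50C	36	37	0.25	0.25	figure
mut	70C	36	37	0.20	0.20	figure
wt	50C	38	40	0.80	0.80	figure
wt	70C	38	40	0.93	0.93	text
mut	50C	38	40	0.50	0.50	figure
mut	70C	38	40	0.45	0.45	figure
wt	50C	37	39	0.02	0.02	text
wt	70C	37	39	0.02	0.02	text
mut	50C	37	39	0.10	0.10	figure
mut	70C	37	39	0.25	0.25	text
wt	50C	42	405	0.02	0.02	text
wt	70C	42	405	0.02	0.02	text
mut	50C	42	405	0.59	0.59	text
mut	70C	42	405	0.74	0.74	text
wt	50C	161	163	0.90	1.74	text
wt	70C	161	163	0.88	1.70	text
mut	50C	161	163	0.45	0.78	text
mut	70C	161	163	0.40	0.75	text
wt	50C	129	165	0.89	0.89	text
wt	70C	129	165	0.24	0.24	text
mut	50C	129	165	0.60	0.60	figure
mut	70C	129	165	0.40	0.40	text
mut	50C	166	167	0.20	0.20	text
mut	70C	166	167	0.20	0.20	text
wt	50C	244	248	0.24	0.24	text
wt	70C	244	248	0.24	0.24	text
mut	50C	244	248	0.95	1.90	text
mut	70C	244	248	0.95	1.90	text
wt	50C	250	254	0.70	0.80	figure
wt	70C	250	254	0.70	0.88	text
mut	50C	250	254	0.75	1.01	text
mut	70C	250	254	0.60	0.78	text
wt	50C	250	253	0.60	0.60	figure
wt	70C	250	253	0.55	0.55	figure
mut	50C	250	253	0.35	0.35	figure
mut	70C	250	253	0.30	0.30	figure
wt	50C	246	254	0.20	0.20	figure
wt	70C	246	254	0.15	0.15	figure
mut	50C	246	254	0.45	0.45	figure
mut	70C	246	254	0.40	0.40	figure
wt	50C	247	251	0.12	0.12	figure
wt	70C	247	251	0.10	0.10	figure
mut	50C	247	251	0.40	0.40	figure
mut	70C	247	251	0.45	0.45	figure
wt	50C	252	256	0.10	0.10	figure
wt	70C	252	256	0.08	0.08	figure
mut	50C	252	256	0.35	0.35	figure
mut	70C	252	256	0.38	0.38	figure
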
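participant	CF_mean	CF_sd	SF_mean	SF_sd
1	0.823	0.004	0.822	0.026
2	0.678	0.033	0.630	0.000
3	0.813	0.101	0.719	0.000
4	0.797	0.002	0.723	0.030
5	0.878	0.006	0.734	0.028
6	0.898	0.016	0.874	0.022
7	0.885	0.038	0.808	0.056
8	0.774	0.036	0.621	0.044
9	0.847	0.034	0.805	0.062
10	0.792	0.041	0.671	0.069
11	0.876	0.011	0.794	0.028
12	0.833	0.012	0.787	0.010
13	0.781	0.024	0.736	0.076
14	0.878	0.051	0.835	0.019
15	0.728	0.052	0.743	0.077
16	0.709	0.074	0.717	0.082
17	0.878	0.051	0.835	0.019
18	0.895	0.012	0.765	0.045
19	0.903	0.027	0.800	0.039
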
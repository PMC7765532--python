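participant	n4_mean	n4_sd	n5_mean	n5_sd	n6_mean	n6_sd	n7_mean	n7_sd	n8_mean	n8_sd	n9_mean	n9_sd
1	0.804	0.064	0.765	0.098	0.787	0.082	0.801	0.087	0.767	0.102	0.780	0.075
2	0.711	0.003	0.665	0.033	0.735	0.018	0.680	0.026	0.658	0.060	0.637	0.041
3	0.759	0.116	0.711	0.075	0.784	0.123	0.762	0.121	0.805	0.114	0.764	0.111
4	0.712	0.096	0.730	0.115	0.710	0.077	0.728	0.100	0.754	0.072	0.719	0.077
5	0.885	0.028	0.865	0.024	0.869	0.016	0.809	0.037	0.862	0.025	0.801	0.019
6	0.873	0.048	0.875	0.042	0.879	0.015	0.875	0.043	0.896	0.023	0.887	0.027
7	0.891	0.021	0.885	0.038	0.861	0.101	0.847	0.045	0.866	0.062	0.854	0.057
8	0.746	0.017	0.774	0.036	0.729	0.019	0.715	0.031	0.726	0.022	0.740	0.022
9	0.840	0.061	0.774	0.012	0.729	0.032	0.715	0.050	0.726	0.061	0.740	0.045
10	0.772	0.039	0.792	0.041	0.776	0.014	0.751	0.036	0.757	0.040	0.759	0.036
11	0.898	0.011	0.876	0.011	0.878	0.023	0.864	0.023	0.877	0.010	0.895	0.007
12	0.810	0.048	0.833	0.012	0.835	0.029	0.764	0.022	0.791	0.030	0.773	0.034
13	0.734	0.044	0.790	0.009	0.787	0.020	0.792	0.024	0.795	0.032	0.732	0.040
14	0.837	0.078	0.878	0.051	0.830	0.075	0.819	0.091	0.852	0.051	0.832	0.027
15	0.741	0.063	0.751	0.071	0.762	0.030	0.756	0.007	0.774	0.060	0.758	0.012
16	0.812	0.102	0.717	0.063	0.738	0.075	0.729	0.085	0.739	0.081	0.755	0.057
17	0.837	0.078	0.878	0.051	0.830	0.075	0.819	0.091	0.852	0.051	0.786	0.027
18	0.912	0.004	0.895	0.012	0.918	0.013	0.900	0.010	0.898	0.006	0.891	0.011
19	0.935	0.005	0.903	0.027	0.910	0.005	0.916	0.002	0.925	0.002	0.912	0.029
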
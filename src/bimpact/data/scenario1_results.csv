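# Published five-year BIA results, scenario 1: abemaciclib uptake rising 20% -> 60%,
# displacing the palbociclib/ribociclib/standard-care mix. One row per (year, arm);
# year-level columns (n, baseline_total, scenario_total, incremental, per_patient)
# repeat on both arm rows. All monetary cells in integer QAR as printed.
scenario_id,year,n,baseline_total,arm_id,arm_label,arm_role,share,arm_cost,scenario_total,incremental,per_patient,source
s1,2024,173,31124763,std_care_mix,PLBO/RIBO/Other Tx,comparator_mix,0.80,24899810,29890060,-1234703,-7137,scenario-1 results table year 1
s1,2024,173,31124763,abma,ABMA,intervention,0.20,4990249,29890060,-1234703,-7137,scenario-1 results table year 1
s1,2025,182,32681001,std_care_mix,PLBO/RIBO/Other Tx,comparator_mix,0.70,22876701,30736344,-1944658,-10685,scenario-1 results table year 2
s1,2025,182,32681001,abma,ABMA,intervention,0.30,7859643,30736344,-1944658,-10685,scenario-1 results table year 2
s1,2026,191,34363178,std_care_mix,PLBO/RIBO/Other Tx,comparator_mix,0.60,20617907,31636839,-2726339,-14274,scenario-1 results table year 3
s1,2026,191,34363178,abma,ABMA,intervention,0.40,11018932,31636839,-2726339,-14274,scenario-1 results table year 3
s1,2027,201,36081336,std_care_mix,PLBO/RIBO/Other Tx,comparator_mix,0.50,18040668,32503017,-3578320,-17803,scenario-1 results table year 4
s1,2027,201,36081336,abma,ABMA,intervention,0.50,14462348,32503017,-3578320,-17803,scenario-1 results table year 4
s1,2028,211,37961416,std_care_mix,PLBO/RIBO/Other Tx,comparator_mix,0.40,15184566,33443687,-4517729,-21411,scenario-1 results table year 5
s1,2028,211,37961416,abma,ABMA,intervention,0.60,18259121,33443687,-4517729,-21411,scenario-1 results table year 5
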
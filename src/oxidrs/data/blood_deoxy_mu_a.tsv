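# reduced (deoxygenated) whole blood, 145 g Hb/L (1/mm)
# SYNTHETIC approximation; substitute your own table for exact literature curves.
# wavelength_nm	mu_a_per_mm
450	32.0934
452	29.8099
454	27.624
456	25.5446
458	23.5805
460	21.7407
462	19.9393
464	18.1557
466	16.4963
468	15.0676
470	13.9762
472	13.125
474	12.3633
476	11.7165
478	11.2104
480	10.8703
482	10.6306
484	10.4181
486	10.2479
488	10.1349
490	10.0939
492	10.1387
494	10.2565
496	10.4224
498	10.6115
500	10.7989
502	10.9982
504	11.2315
506	11.4861
508	11.7495
510	12.0091
512	12.257
514	12.5016
516	12.7555
518	13.0311
520	13.341
522	13.6821
524	14.0544
526	14.4749
528	14.9608
530	15.5291
532	16.2955
534	17.2971
536	18.4332
538	19.6029
540	20.7054
542	21.7747
544	22.878
546	23.9644
548	24.9826
550	25.8818
552	26.7659
554	27.4852
556	27.7131
558	27.8077
560	27.8426
562	27.3652
564	26.3695
566	25.4381
568	24.4904
570	23.3309
572	21.5518
574	19.3778
576	17.5996
578	16.4719
580	15.5291
582	14.6182
584	13.7635
586	12.9409
588	12.1529
590	11.388
592	10.5965
594	9.78402
596	8.98826
598	8.24682
600	7.59733
602	7.02131
604	6.48157
606	5.98775
608	5.54947
610	5.17635
612	4.86602
614	4.59838
616	4.35649
618	4.12343
620	3.88227
622	3.61499
624	3.33281
626	3.06257
628	2.83112
630	2.6653
632	2.55396
634	2.46348
636	2.38705
638	2.31787
640	2.24913
642	2.181
644	2.1174
646	2.05706
648	1.99872
650	1.94113
652	1.8834
654	1.82625
656	1.7709
658	1.71855
660	1.67041
662	1.62641
664	1.5853
666	1.54646
668	1.50929
670	1.47319
672	1.43914
674	1.40741
676	1.37635
678	1.3443
680	1.30962
682	1.27074
684	1.22857
686	1.18512
688	1.14245
690	1.10256
692	1.06435
694	1.02634
696	0.990046
698	0.956974
700	0.928638
702	0.905348
704	0.885308
706	0.866872
708	0.848391
710	0.828217
712	0.806385
714	0.783948
716	0.76078
718	0.736755
720	0.711749
722	0.680707
724	0.643618
726	0.607918
728	0.581045
730	0.570434
732	0.570722
734	0.571566
736	0.57294
738	0.574815
740	0.577163
742	0.589837
744	0.618097
746	0.655031
748	0.693729
750	0.727278
752	0.759893
754	0.796206
756	0.829928
758	0.854772
760	0.864451
762	0.859052
764	0.845147
766	0.826178
768	0.805584
770	0.786806
772	0.770209
774	0.753459
776	0.735949
778	0.717072
780	0.69622
782	0.670468
784	0.638584
786	0.602493
788	0.564122
790	0.525399
792	0.488249
794	0.4546
796	0.426377
798	0.405509
800	0.393921
802	0.38784
804	0.382235
806	0.377139
808	0.372589
810	0.36862
812	0.365266
814	0.362564
816	0.360549
818	0.359257
820	0.358721
822	0.358582
824	0.358454
826	0.358336
828	0.358229
830	0.358131
832	0.358044
834	0.357967
836	0.3579
838	0.357842
840	0.357794
842	0.357755
844	0.357724
846	0.357703
848	0.35769
850	0.357686
852	0.357717
854	0.357809
856	0.35796
858	0.358168
860	0.358432
862	0.35875
864	0.35912
866	0.35954
868	0.360009
870	0.360525
872	0.361086
874	0.36169
876	0.362336
878	0.363022
880	0.363746
882	0.364506
884	0.365301
886	0.366129
888	0.366988
890	0.367876
892	0.368792
894	0.369734
896	0.3707
898	0.371688
900	0.372697
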